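"""Phenotype gating from multiplex marker intensities.

Cells carrying CD4/PD1/FOXP3/Ki67 staining intensities are classified into
T-cell subsets with the rule table used for multiplexed tissue sections:

* Tfh  — CD4+, PD1 at high level, FOXP3 negative
* Tfr  — CD4+, PD1 at high level, FOXP3 positive
* Treg — CD4+, PD1 below the high threshold, FOXP3 positive
* other — everything else

Ki67 positivity is flagged independently of the subset call, and the
single-marker surrogate populations (PD1-high regardless of CD4/FOXP3;
FOXP3+ regardless of PD1) are exposed through per-marker flags.

Threshold conventions (documented, fixed): a marker is positive/high when
its intensity is ``>=`` the threshold, negative when ``<``; boundary cells
are positive. The PD1-high threshold is calibrated as a low quantile
(default 5th percentile, linear interpolation between order statistics) of
a reference PD1-high population — follicular-helper cells of tonsillar
germinal centres. When no reference or explicit threshold is given, each
channel's threshold defaults to the midpoint (in log-intensity) between the
two largest modes of a kernel density estimate of that channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import MARKER_CHANNELS

PHENOTYPES = ("Tfh", "Tfr", "Treg", "other")

#: Surrogate/population selectors usable wherever a phenotype is requested.
POPULATION_FLAGS = {
    "PD1hi": "pd1_hi",
    "FOXP3pos": "foxp3_pos",
    "Ki67pos": "ki67_pos",
    "CD4pos": "cd4_pos",
}


class GatingError(ValueError):
    """Raised for unusable gating inputs or configuration."""


@dataclass(frozen=True)
class GatingConfig:
    """Positivity thresholds per marker plus the PD1-high calibration quantile.

    ``thresholds`` maps channel name to intensity threshold; channels left
    unset are calibrated from the data (PD1 from a reference population if
    one is supplied, otherwise by bimodality split, like the rest).
    """

    thresholds: dict[str, float] = field(default_factory=dict)
    reference_quantile: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.reference_quantile < 1.0):
            raise GatingError("reference_quantile must lie in (0, 1)")
        for ch, t in self.thresholds.items():
            if not t > 0:
                raise GatingError(f"threshold for {ch} must be > 0, got {t}")

    def with_threshold(self, channel: str, value: float) -> "GatingConfig":
        t = dict(self.thresholds)
        t[channel] = float(value)
        return replace(self, thresholds=t)


def calibrate_pd1_threshold(
    reference: pd.DataFrame, config: GatingConfig | None = None
) -> GatingConfig:
    """Set the PD1-high threshold from a reference PD1-high population.

    The threshold is the ``reference_quantile``-quantile (linear
    interpolation between order statistics) of the reference PD1 channel,
    so nearly the whole reference population sits at or above it. The input
    config is not modified; a new one is returned.
    """
    config = GatingConfig() if config is None else config
    if reference is None or len(reference) == 0:
        raise GatingError("reference table is empty; cannot calibrate PD1 threshold")
    if "PD1" not in reference.columns:
        raise GatingError("reference table has no PD1 channel")
    pd1 = np.asarray(reference["PD1"], dtype=float)
    if not (pd1 > 0).any():
        raise GatingError("reference PD1 channel is all zero; cannot calibrate")
    tau = float(np.quantile(pd1, config.reference_quantile, method="linear"))
    return config.with_threshold("PD1", tau)


def bimodal_threshold(values: np.ndarray) -> float:
    """Split a bimodal positive channel at the midpoint between its two modes.

    A Gaussian kernel density estimate of log-intensity is evaluated on a
    fine grid; the two local maxima with the highest density are taken as
    the negative and positive modes and the threshold is the midpoint of
    their locations in log space (returned on the intensity scale).
    """
    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    if len(values) < 10:
        raise GatingError("too few positive intensities for bimodality split")
    logv = np.log(values)
    if np.ptp(logv) < 1e-9:
        raise GatingError("constant channel; supply an explicit threshold")
    kde = stats.gaussian_kde(logv)
    grid = np.linspace(logv.min(), logv.max(), 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if len(peaks) < 2:
        raise GatingError(
            "channel does not look bimodal; supply an explicit threshold"
        )
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = np.sort(grid[top2])
    return float(np.exp((lo + hi) / 2.0))


def resolve_thresholds(
    cells: pd.DataFrame,
    config: GatingConfig | None = None,
    reference: pd.DataFrame | None = None,
) -> GatingConfig:
    """Fill in every unset channel threshold.

    PD1 is calibrated from ``reference`` when one is supplied; any channel
    still unset falls back to the per-channel bimodality split of the cell
    table itself.
    """
    config = GatingConfig() if config is None else config
    if "PD1" not in config.thresholds and reference is not None:
        config = calibrate_pd1_threshold(reference, config)
    for ch in MARKER_CHANNELS:
        if ch not in config.thresholds:
            if ch not in cells.columns:
                raise GatingError(f"missing marker channel: {ch}")
            config = config.with_threshold(ch, bimodal_threshold(cells[ch].to_numpy()))
    return config


def gate_cells(cells: pd.DataFrame, config: GatingConfig) -> pd.DataFrame:
    """Apply the subset rule table to every cell.

    Requires a fully resolved config (every channel thresholded; see
    :func:`resolve_thresholds`). Returns one row per cell with columns
    ``cell_id, x, y, phenotype, cd4_pos, pd1_hi, foxp3_pos, ki67_pos`` (and
    ``true_label`` passed through when present). Pure function: identical
    inputs give identical calls.
    """
    for ch in MARKER_CHANNELS:
        if ch not in cells.columns:
            raise GatingError(f"missing marker channel: {ch}")
        if ch not in config.thresholds:
            raise GatingError(f"no threshold for channel {ch}; resolve config first")
    cd4 = cells["CD4"].to_numpy(float) >= config.thresholds["CD4"]
    pd1 = cells["PD1"].to_numpy(float) >= config.thresholds["PD1"]
    foxp3 = cells["FOXP3"].to_numpy(float) >= config.thresholds["FOXP3"]
    ki67 = cells["Ki67"].to_numpy(float) >= config.thresholds["Ki67"]

    phenotype = np.full(len(cells), "other", dtype=object)
    phenotype[cd4 & pd1 & ~foxp3] = "Tfh"
    phenotype[cd4 & pd1 & foxp3] = "Tfr"
    phenotype[cd4 & ~pd1 & foxp3] = "Treg"

    calls = pd.DataFrame(
        {
            "cell_id": cells["cell_id"].to_numpy(),
            "x": cells["x"].to_numpy(float),
            "y": cells["y"].to_numpy(float),
            "phenotype": phenotype,
            "cd4_pos": cd4,
            "pd1_hi": pd1,
            "foxp3_pos": foxp3,
            "ki67_pos": ki67,
        }
    )
    if "true_label" in cells.columns:
        calls["true_label"] = cells["true_label"].to_numpy()
    return calls


def select_population(calls: pd.DataFrame, name: str) -> pd.DataFrame:
    """Rows belonging to a subset phenotype or single-marker population.

    ``name`` is one of the subset phenotypes (Tfh, Tfr, Treg, other) or a
    flag population (PD1hi, FOXP3pos, Ki67pos, CD4pos).
    """
    if name in POPULATION_FLAGS:
        return calls[calls[POPULATION_FLAGS[name]]]
    if name in PHENOTYPES:
        return calls[calls["phenotype"] == name]
    raise GatingError(f"unknown population: {name!r}")


def subset_summary(calls: pd.DataFrame) -> dict:
    """Counts, CD4+ fractions and the PD1hi:FOXP3+ ratio for one case.

    Fractions of CD4+ cells are ``nan`` (undefined) when no cell is CD4+;
    the PD1hi:FOXP3+ ratio is ``inf`` when FOXP3+ is empty but PD1hi is
    not, and ``nan`` when both are empty.
    """
    if len(calls) == 0:
        raise GatingError("no phenotype calls to summarise")
    n_cd4 = int(calls["cd4_pos"].sum())
    counts = {ph: int((calls["phenotype"] == ph).sum()) for ph in PHENOTYPES}
    n_pd1hi = int(calls["pd1_hi"].sum())
    n_foxp3 = int(calls["foxp3_pos"].sum())
    n_ki67 = int(calls["ki67_pos"].sum())
    n_cd4_pd1hi = int((calls["cd4_pos"] & calls["pd1_hi"]).sum())

    def frac(k: int, n: int) -> float:
        return k / n if n > 0 else float("nan")

    subset_total = counts["Tfh"] + counts["Tfr"] + counts["Treg"]
    if n_foxp3 > 0:
        ratio = n_pd1hi / n_foxp3
    else:
        ratio = float("inf") if n_pd1hi > 0 else float("nan")
    return {
        "n_cells": int(len(calls)),
        "n_cd4": n_cd4,
        "counts": counts,
        "n_pd1hi": n_pd1hi,
        "n_foxp3pos": n_foxp3,
        "n_ki67pos": n_ki67,
        "fraction_of_cd4": {ph: frac(counts[ph], n_cd4) for ph in PHENOTYPES},
        "subset_fraction_of_cd4": frac(subset_total, n_cd4),
        "tfr_fraction_of_cd4_pd1hi": frac(counts["Tfr"], n_cd4_pd1hi),
        "pd1hi_foxp3_ratio": ratio,
    }


def surrogate_agreement(
    per_case_calls: dict[str, pd.DataFrame],
    surrogate: str = "PD1hi",
    subset: str = "Tfh",
) -> dict:
    """Least-squares agreement between single-marker and multi-marker counts.

    Regresses the multi-marker subset count on the single-marker surrogate
    count across cases and reports R², slope, intercept and p-value. At
    least three cases are required; a constant predictor leaves R²
    undefined (``nan``) with ``degenerate=True``.
    """
    if len(per_case_calls) < 3:
        raise GatingError(
            f"surrogate regression needs >=3 cases, got {len(per_case_calls)}"
        )
    case_ids = list(per_case_calls)
    x = np.array(
        [len(select_population(per_case_calls[c], surrogate)) for c in case_ids],
        dtype=float,
    )
    y = np.array(
        [len(select_population(per_case_calls[c], subset)) for c in case_ids],
        dtype=float,
    )
    if np.ptp(x) == 0:
        return {
            "surrogate": surrogate,
            "subset": subset,
            "n_cases": len(case_ids),
            "r_squared": float("nan"),
            "slope": float("nan"),
            "intercept": float("nan"),
            "p_value": float("nan"),
            "degenerate": True,
        }
    fit = stats.linregress(x, y)
    return {
        "surrogate": surrogate,
        "subset": subset,
        "n_cases": len(case_ids),
        "r_squared": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "p_value": float(fit.pvalue),
        "degenerate": False,
    }
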