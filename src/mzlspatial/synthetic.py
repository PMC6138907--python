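"""Seeded generators for marked planar point patterns with marker intensities.

The study's raw cell coordinates are not deposited, so every downstream
stage of the pipeline is exercised on synthetic marked point patterns that
carry the statistical structure the analysis assumes:

* a clustered phenotype (follicular-helper / PD1-high analogue) drawn from
  a Thomas (Neyman–Scott) cluster process,
* a near-random phenotype (regulatory / FOXP3+ analogue) drawn from a
  homogeneous Poisson process (CSR),
* a proliferating (Ki-67+) population whose clusters either share parents
  with the clustered phenotype ("linked") or are drawn independently,
* per-cell marker intensities (CD4, PD1, FOXP3, Ki67) drawn from
  log-normal per-phenotype channel models, giving a bimodal PD1 channel
  whenever PD1-high and PD1-low phenotypes coexist.

All randomness flows through :class:`numpy.random.Generator` streams spawned
from a single seed, so a fixed seed yields bit-identical output and adding a
stage does not perturb earlier draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Window

MARKER_CHANNELS = ("CD4", "PD1", "FOXP3", "Ki67")

#: σ-multiple by which the parent window is buffered so clusters straddling
#: the boundary are not edge-thinned (offspring are clipped to the window).
PARENT_BUFFER_SIGMAS = 4.0


class SimulationError(ValueError):
    """Raised for invalid simulator configurations."""


@dataclass(frozen=True)
class ThomasParams:
    """Parameters of a Thomas (Neyman–Scott) cluster process.

    parent_intensity
        κ, cluster parents per μm².
    mean_offspring
        μ_c, mean offspring per parent (Poisson).
    cluster_sd
        σ, isotropic Gaussian offspring displacement scale in μm.
    """

    parent_intensity: float
    mean_offspring: float
    cluster_sd: float

    def __post_init__(self) -> None:
        if not (
            self.parent_intensity > 0
            and self.mean_offspring > 0
            and self.cluster_sd > 0
        ):
            raise SimulationError(
                "Thomas parameters parent_intensity, mean_offspring, cluster_sd "
                "must all be > 0"
            )

    @property
    def intensity(self) -> float:
        """Stationary point intensity κ·μ_c (points per μm²)."""
        return self.parent_intensity * self.mean_offspring


@dataclass(frozen=True)
class IntensityModel:
    """Log-normal intensity model for one marker channel of one phenotype.

    ``meanlog``/``sdlog`` are the location and scale of log-intensity;
    intensities are strictly positive and right-skewed, matching
    immunohistochemical signal behaviour.
    """

    meanlog: float
    sdlog: float

    def __post_init__(self) -> None:
        if self.sdlog <= 0:
            raise SimulationError("sdlog must be > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.lognormal(self.meanlog, self.sdlog, size=n)


# Default channel models: log-intensity locations separated by 12 scale
# units (|Δmeanlog|/sdlog = 3.0/0.25) between the "high" and "low" state of
# every marker, so threshold gating is essentially exact.
LOW = IntensityModel(meanlog=1.0, sdlog=0.25)
HIGH = IntensityModel(meanlog=4.0, sdlog=0.25)

#: Per-phenotype channel models for the default scenario. Phenotypes:
#: Tfh (CD4+ PD1hi FOXP3−), Treg (CD4+ PD1lo FOXP3+), Tfr (CD4+ PD1hi
#: FOXP3+), Bprolif (CD4− Ki67+ proliferating B-cell analogue) and a CD4+
#: double-negative background.
DEFAULT_INTENSITY_MODELS: dict[str, dict[str, IntensityModel]] = {
    "Tfh": {"CD4": HIGH, "PD1": HIGH, "FOXP3": LOW, "Ki67": LOW},
    "Tfr": {"CD4": HIGH, "PD1": HIGH, "FOXP3": HIGH, "Ki67": LOW},
    "Treg": {"CD4": HIGH, "PD1": LOW, "FOXP3": HIGH, "Ki67": LOW},
    "Bprolif": {"CD4": LOW, "PD1": LOW, "FOXP3": LOW, "Ki67": HIGH},
    "background": {"CD4": HIGH, "PD1": LOW, "FOXP3": LOW, "Ki67": LOW},
}

#: Phenotype call and Ki67 flag that exact gating should produce for each
#: ground-truth label of the default models.
EXPECTED_CALLS: dict[str, tuple[str, bool]] = {
    "Tfh": ("Tfh", False),
    "Tfr": ("Tfr", False),
    "Treg": ("Treg", False),
    "Bprolif": ("other", True),
    "background": ("other", False),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration for one synthetic pattern.

    ``process_kind`` selects the generator: ``csr`` (homogeneous Poisson at
    ``intensity`` points/μm²), ``thomas`` (cluster process with ``thomas``
    parameters), ``linked_bivariate``/``independent_bivariate`` (two labelled
    classes, sharing or not sharing cluster parents) and ``full_tissue``
    (the four-phenotype default scenario).
    """

    window: Window
    seed: int
    process_kind: str = "csr"
    intensity: float | None = None  # λ for CSR, cells/μm²
    thomas: ThomasParams | None = None
    label: str = "cell"
    # bivariate settings: class labels and per-class mean offspring
    label_a: str = "Tfh"
    label_b: str = "Bprolif"
    mean_offspring_b: float | None = None
    cluster_sd_b: float | None = None
    intensity_models: dict[str, dict[str, IntensityModel]] = field(
        default_factory=lambda: DEFAULT_INTENSITY_MODELS
    )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed))


@dataclass
class LabeledPattern:
    """A marked point pattern: coordinates, phenotype labels, optional parents."""

    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray
    window: Window
    parent_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (len(self.x) == len(self.y) == len(self.labels)):
            raise SimulationError("points and labels must have equal length")
        if len(self.x) and not self.window.contains(self.x, self.y).all():
            raise SimulationError("pattern contains points outside its window")

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, label: str) -> "LabeledPattern":
        m = self.labels == label
        return LabeledPattern(
            self.x[m],
            self.y[m],
            self.labels[m],
            self.window,
            None if self.parent_ids is None else self.parent_ids[m],
        )

    @staticmethod
    def concatenate(parts: list["LabeledPattern"]) -> "LabeledPattern":
        if not parts:
            raise SimulationError("cannot concatenate zero patterns")
        window = parts[0].window
        pid_parts = []
        offset = 0
        for p in parts:
            if p.parent_ids is None:
                pid_parts.append(np.full(len(p), -1, dtype=int))
            else:
                pid = p.parent_ids.copy()
                shift = pid >= 0
                pid[shift] += offset
                pid_parts.append(pid)
                if shift.any():
                    offset += int(p.parent_ids[shift].max()) + 1
        return LabeledPattern(
            np.concatenate([p.x for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.labels for p in parts]),
            window,
            np.concatenate(pid_parts),
        )


def _uniform_in(window: Window, n: int, rng: np.random.Generator):
    x = rng.uniform(window.x_min, window.x_max, size=n)
    y = rng.uniform(window.y_min, window.y_max, size=n)
    return x, y


def simulate_csr(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> LabeledPattern:
    """Homogeneous Poisson pattern — the complete-spatial-randomness null.

    The point count is Poisson(λ·|A|) and coordinates are i.i.d. uniform
    on the window.
    """
    if config.intensity is None or config.intensity <= 0:
        raise SimulationError("CSR simulation requires intensity λ > 0")
    rng = config.rng() if rng is None else rng
    n = rng.poisson(config.intensity * config.window.area)
    x, y = _uniform_in(config.window, n, rng)
    labels = np.full(n, config.label, dtype=object)
    return LabeledPattern(x, y, labels, config.window)


def _thomas_points(
    window: Window,
    params: ThomasParams,
    rng: np.random.Generator,
    parents: tuple[np.ndarray, np.ndarray] | None = None,
    mean_offspring: float | None = None,
    cluster_sd: float | None = None,
):
    """Offspring of a Thomas process clipped to ``window``.

    Parents are drawn on the window buffered by ``PARENT_BUFFER_SIGMAS``·σ
    (unless supplied), so clusters whose parents fall just outside the
    tissue window still contribute offspring: the retained pattern is an
    unbiased restriction of the stationary process.
    """
    mu = params.mean_offspring if mean_offspring is None else mean_offspring
    sd = params.cluster_sd if cluster_sd is None else cluster_sd
    if sd > window.shorter_side / 2:
        warnings.warn(
            "cluster_sd exceeds half the shorter window side; "
            "cluster structure is unresolvable at this scale",
            stacklevel=3,
        )
    if parents is None:
        buffered = window.expand(PARENT_BUFFER_SIGMAS * sd)
        n_parents = rng.poisson(params.parent_intensity * buffered.area)
        parents = _uniform_in(buffered, n_parents, rng)
    px, py = parents
    counts = rng.poisson(mu, size=len(px))
    parent_ids = np.repeat(np.arange(len(px)), counts)
    x = np.repeat(px, counts) + rng.normal(0.0, sd, size=counts.sum())
    y = np.repeat(py, counts) + rng.normal(0.0, sd, size=counts.sum())
    keep = window.contains(x, y)
    return x[keep], y[keep], parent_ids[keep], (px, py)


def simulate_thomas(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> LabeledPattern:
    """Thomas (Neyman–Scott) cluster pattern emulating a clustered phenotype."""
    if config.thomas is None:
        raise SimulationError("Thomas simulation requires thomas parameters")
    rng = config.rng() if rng is None else rng
    x, y, pid, _ = _thomas_points(config.window, config.thomas, rng)
    labels = np.full(len(x), config.label, dtype=object)
    return LabeledPattern(x, y, labels, config.window, pid)


def simulate_bivariate(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> LabeledPattern:
    """Two labelled classes, with shared ("linked") or independent parents.

    In the linked process both classes emit offspring around the same
    cluster parents, forcing co-location — the mechanism hypothesised for
    proliferating B-cells around follicular-helper T-cells. The independent
    process draws a fresh parent set for the second class, so any apparent
    co-localization is coincidental.
    """
    if config.process_kind not in ("linked_bivariate", "independent_bivariate"):
        raise SimulationError(f"not a bivariate process kind: {config.process_kind}")
    if config.thomas is None:
        raise SimulationError("bivariate simulation requires thomas parameters")
    rng = config.rng() if rng is None else rng
    mu_b = (
        config.thomas.mean_offspring
        if config.mean_offspring_b is None
        else config.mean_offspring_b
    )
    sd_b = (
        config.thomas.cluster_sd if config.cluster_sd_b is None else config.cluster_sd_b
    )
    xa, ya, pa, parents = _thomas_points(config.window, config.thomas, rng)
    if config.process_kind == "linked_bivariate":
        xb, yb, pb, _ = _thomas_points(
            config.window,
            config.thomas,
            rng,
            parents=parents,
            mean_offspring=mu_b,
            cluster_sd=sd_b,
        )
    else:
        if mu_b > 0:
            xb, yb, pb, _ = _thomas_points(
                config.window,
                config.thomas,
                rng,
                mean_offspring=mu_b,
                cluster_sd=sd_b,
            )
        else:  # degenerate: empty second class
            xb = np.empty(0)
            yb = np.empty(0)
            pb = np.empty(0, dtype=int)
    a = LabeledPattern(
        xa, ya, np.full(len(xa), config.label_a, dtype=object), config.window, pa
    )
    b = LabeledPattern(
        xb, yb, np.full(len(xb), config.label_b, dtype=object), config.window, pb
    )
    return LabeledPattern.concatenate([a, b])


def attach_intensities(
    pattern: LabeledPattern,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-cell marker intensities from the per-phenotype channel models.

    Returns a cell table with columns ``cell_id, x, y, CD4, PD1, FOXP3,
    Ki67, true_label, parent_id``; ground-truth labels are retained so
    gating accuracy can be scored. Draws are made label-block-wise in a
    fixed channel order, so a fixed seed yields an identical table.
    """
    rng = config.rng() if rng is None else rng
    models = config.intensity_models
    present = pd.unique(pd.Series(pattern.labels, dtype=object))
    for lab in present:
        if lab not in models:
            raise SimulationError(f"no intensity model for phenotype {lab!r}")
        missing = [c for c in MARKER_CHANNELS if c not in models[lab]]
        if missing:
            raise SimulationError(
                f"phenotype {lab!r} lacks channel models for {missing}"
            )
    n = len(pattern)
    table = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x": pattern.x,
            "y": pattern.y,
        }
    )
    for ch in MARKER_CHANNELS:
        table[ch] = np.zeros(n)
    # iterate labels in declared model order for draw-order stability
    for lab in [l for l in models if l in set(present)]:
        m = pattern.labels == lab
        for ch in MARKER_CHANNELS:
            table.loc[m, ch] = models[lab][ch].sample(rng, int(m.sum()))
    table["true_label"] = pattern.labels
    table["parent_id"] = (
        np.full(n, -1, dtype=int) if pattern.parent_ids is None else pattern.parent_ids
    )
    return table


# --------------------------------------------------------------------------
# Default multi-phenotype tissue scenario
# --------------------------------------------------------------------------

#: Default parameters of the four-phenotype tissue scenario (2.25 mm² window):
#: a Thomas-clustered Tfh analogue, a CSR Treg analogue, a proliferating
#: B-cell class linked to the Tfh parents, and a CD4+ CSR background sized so
#: the Tfh+Treg share of CD4+ cells is ≈16% — the subset share scale reported
#: for this tissue type.
FULL_TISSUE_DEFAULTS = {
    "window": Window(0.0, 0.0, 1500.0, 1500.0),
    "tfh": ThomasParams(parent_intensity=2e-5, mean_offspring=25.0, cluster_sd=20.0),
    "treg_intensity": 5e-4,
    "bprolif_mean_offspring": 40.0,
    "bprolif_cluster_sd": 25.0,
    "background_intensity": 5.1e-3,
}


def simulate_full_tissue(
    seed: int,
    window: Window | None = None,
    linked: bool = True,
    params: dict | None = None,
) -> tuple[LabeledPattern, pd.DataFrame]:
    """One synthetic tissue case with all four phenotypes plus intensities.

    Returns the labelled pattern and the cell table with marker channels.
    ``linked=False`` draws the proliferating class from its own parent set,
    severing the Tfh–proliferation association while keeping all marginal
    intensities equal.
    """
    p = dict(FULL_TISSUE_DEFAULTS)
    if params:
        p.update(params)
    window = p["window"] if window is None else window
    ss = np.random.SeedSequence(seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in ss]
    tfh_cfg = SimulationConfig(
        window=window,
        seed=seed,
        process_kind="linked_bivariate" if linked else "independent_bivariate",
        thomas=p["tfh"],
        label_a="Tfh",
        label_b="Bprolif",
        mean_offspring_b=p["bprolif_mean_offspring"],
        cluster_sd_b=p["bprolif_cluster_sd"],
    )
    tfh_b = simulate_bivariate(tfh_cfg, rng=rngs[0])
    treg = simulate_csr(
        SimulationConfig(
            window=window, seed=seed, intensity=p["treg_intensity"], label="Treg"
        ),
        rng=rngs[1],
    )
    bg = simulate_csr(
        SimulationConfig(
            window=window,
            seed=seed,
            intensity=p["background_intensity"],
            label="background",
        ),
        rng=rngs[2],
    )
    pattern = LabeledPattern.concatenate([tfh_b, treg, bg])
    cfg = SimulationConfig(window=window, seed=seed, process_kind="full_tissue")
    table = attach_intensities(pattern, cfg, rng=rngs[3])
    return pattern, table


def simulate_reference_tonsil(seed: int, n: int = 2000) -> pd.DataFrame:
    """Reference PD1-high population used to calibrate the PD1-high threshold.

    Emulates follicular-helper cells of tonsillar germinal centres from
    healthy tissue: every cell is drawn from the PD1-high intensity model.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    window = Window(0.0, 0.0, 500.0, 500.0)
    x, y = _uniform_in(window, n, rng)
    table = pd.DataFrame({"cell_id": np.arange(n), "x": x, "y": y})
    models = DEFAULT_INTENSITY_MODELS["Tfh"]
    for ch in MARKER_CHANNELS:
        table[ch] = models[ch].sample(rng, n)
    return table
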