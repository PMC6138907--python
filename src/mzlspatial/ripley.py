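"""Ripley's K function, CSR comparison and the scalar cluster score.

Ripley's K summarises second-order spatial structure: K(r) is the expected
number of further points within distance r of a typical point, divided by
the intensity. Under complete spatial randomness (CSR, a homogeneous
Poisson process) K(r) = πr²; values above πr² indicate clustering, below
it regularity.

The estimator used here is

    K̂(r) = |A| / (n(n−1)) · Σ_{i≠j} w_ij · 1(d_ij ≤ r)

with ``w_ij`` an edge-correction weight. The default is the translation
correction, exact for rectangular windows:
w_ij = |A| / ((W−|dx_ij|)(H−|dy_ij|)). ``correction="none"`` (w_ij = 1)
is provided for oracle tests.

The deviation of the observed curve from the CSR curve is reduced to a
single dimensionless cluster score,

    score = ∫(K̂(r) − πr²) dr / ∫ πr² dr     (trapezoidal, over the grid),

which is 0 in expectation under CSR, positive for clustering (e.g. 1 when
K̂ = 2πr² everywhere) and negative for regularity; normalising by the CSR
integral makes it window-scale-free. Case-level scores are compared between
two phenotypes with a two-sided Mann-Whitney rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .geometry import Window

CORRECTIONS = ("translation", "none")

#: Largest allowed r as a fraction of the shorter window side; beyond this
#: the edge correction degrades badly.
MAX_RADIUS_FRACTION = 0.25
DEFAULT_N_RADII = 50


class RipleyError(ValueError):
    """Raised for unusable K-function inputs."""


@dataclass
class KFunctionResult:
    """Observed K, its CSR reference πr² and the scalar cluster score."""

    radii: np.ndarray
    k_obs: np.ndarray
    k_csr: np.ndarray
    n_points: int
    correction: str
    window: Window
    cluster_score: float

    def to_dict(self) -> dict:
        return {
            "radii": [float(v) for v in self.radii],
            "k_obs": [float(v) for v in self.k_obs],
            "k_csr": [float(v) for v in self.k_csr],
            "n_points": self.n_points,
            "correction": self.correction,
            "window": self.window.to_dict(),
            "cluster_score": self.cluster_score,
        }


def default_radii(window: Window, n_radii: int = DEFAULT_N_RADII) -> np.ndarray:
    """Evenly spaced radii from 0 to a quarter of the shorter window side."""
    return np.linspace(0.0, MAX_RADIUS_FRACTION * window.shorter_side, n_radii)


def ripley_k(
    x,
    y,
    window: Window,
    radii=None,
    correction: str = "translation",
) -> KFunctionResult:
    """Estimate Ripley's K on a radius grid and score the CSR deviation.

    Pair distances are gathered with a k-d tree restricted to the largest
    radius, weighted by the chosen edge correction, and accumulated into a
    non-decreasing step estimate evaluated on the grid. Deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2:
        raise RipleyError(f"K estimation needs >=2 points, got {n}")
    if not window.contains(x, y).all():
        raise RipleyError("points outside the observation window")
    if correction not in CORRECTIONS:
        raise RipleyError(f"unknown edge correction: {correction!r}")
    radii = default_radii(window) if radii is None else np.asarray(radii, dtype=float)
    if len(radii) < 2 or np.any(np.diff(radii) <= 0) or radii[0] < 0:
        raise RipleyError("radius grid must be strictly increasing with r[0] >= 0")
    r_max = float(radii[-1])
    guard = MAX_RADIUS_FRACTION * window.shorter_side
    if r_max > guard * (1 + 1e-9):
        raise RipleyError(
            f"max radius {r_max:g} exceeds the guard {guard:g} "
            f"(= {MAX_RADIUS_FRACTION} of the shorter window side)"
        )

    # Gather pair separations within r_max: a dense pdist for moderate n,
    # a k-d tree restricted to r_max for large patterns. Both are exact.
    if n * (n - 1) // 2 <= 8_000_000:
        from scipy.spatial.distance import pdist

        d = pdist(np.column_stack([x, y]))
        adx = pdist(x[:, None], "cityblock")
        ady = pdist(y[:, None], "cityblock")
        within = d <= r_max
        d, adx, ady = d[within], adx[within], ady[within]
    else:
        pts = np.column_stack([x, y])
        pairs = cKDTree(pts).query_pairs(r_max, output_type="ndarray")
        adx = np.abs(x[pairs[:, 0]] - x[pairs[:, 1]])
        ady = np.abs(y[pairs[:, 0]] - y[pairs[:, 1]])
        d = np.hypot(adx, ady)
    if len(d):
        if correction == "translation":
            w = window.area / ((window.width - adx) * (window.height - ady))
        else:
            w = np.ones_like(d)
        # smallest radius index covering each pair (d <= radii[idx]); O(N)
        idx = np.searchsorted(radii, d, side="left")
        ok = idx < len(radii)
        binned = np.bincount(idx[ok], weights=w[ok], minlength=len(radii))
        # each unordered pair counts twice in Σ_{i≠j}
        sums = 2.0 * np.cumsum(binned)
    else:
        sums = np.zeros_like(radii)
    k_obs = window.area / (n * (n - 1)) * sums
    k_csr = np.pi * radii**2
    result = KFunctionResult(
        radii=radii,
        k_obs=k_obs,
        k_csr=k_csr,
        n_points=n,
        correction=correction,
        window=window,
        cluster_score=float("nan"),
    )
    result.cluster_score = cluster_score(result)
    return result


def cluster_score(result: KFunctionResult) -> float:
    """Normalised integrated deviation of K̂ from the CSR curve.

    Trapezoidal ∫(K̂ − πr²)dr divided by ∫πr²dr over the common grid;
    dimensionless, 0 for CSR, 1 when K̂ = 2πr².
    """
    r = np.asarray(result.radii, dtype=float)
    k_obs = np.asarray(result.k_obs, dtype=float)
    k_csr = np.asarray(result.k_csr, dtype=float)
    if len(r) < 2 or len(k_obs) != len(r) or len(k_csr) != len(r):
        raise RipleyError("K curves must share a common radius grid with >=2 radii")
    denom = np.trapezoid(k_csr, r)
    if denom <= 0:
        raise RipleyError("degenerate radius grid: CSR integral is zero")
    return float(np.trapezoid(k_obs - k_csr, r) / denom)


def compare_cluster_scores(scores_a, scores_b) -> dict:
    """Medians of two groups of case-level cluster scores and a rank-sum test.

    Two-sided Mann-Whitney U with tie correction; identical groups give
    p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise RipleyError("both score groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        u = len(a) * len(b) / 2.0
        p = 1.0
    else:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "u_statistic": float(u),
        "p_value": float(min(p, 1.0)),
    }
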