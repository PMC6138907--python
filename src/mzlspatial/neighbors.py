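"""Cross-type nearest-neighbour distance analysis.

For each query cell (e.g. a Ki67− PD1-high T-cell) the Euclidean distance
to the nearest target cell (e.g. the nearest Ki67+ proliferating cell) is
computed exactly with a k-d tree; the per-query distances are summarised by
their median and two query phenotypes are compared with a two-sided
Mann-Whitney rank-sum test. Large query populations can be subsampled
(seeded, without replacement, optionally stratified proportionally across
cases) before the distances are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree


class NeighborError(ValueError):
    """Raised for unusable nearest-neighbour inputs."""


@dataclass
class NNResult:
    """Cross-type nearest-neighbour distances for one query/target pair."""

    query: str
    target: str
    distances: np.ndarray
    n_query: int
    n_target: int
    sample_size: int | None = None
    seed: int | None = None

    @property
    def median(self) -> float:
        return float(np.median(self.distances))

    def to_dict(self, keep_distances: bool = False) -> dict:
        d = {
            "query": self.query,
            "target": self.target,
            "n_query": self.n_query,
            "n_target": self.n_target,
            "n_distances": int(len(self.distances)),
            "median": self.median,
            "mean": float(np.mean(self.distances)),
            "sample_size": self.sample_size,
            "seed": self.seed,
        }
        if keep_distances:
            d["distances"] = [float(v) for v in self.distances]
        return d


def cross_nn_distances(
    query_x,
    query_y,
    target_x,
    target_y,
    query: str = "query",
    target: str = "target",
) -> NNResult:
    """Exact distance from every query cell to its nearest target cell.

    Coincident query/target locations give distance 0. The k-d tree query
    is exact (no approximation), so results equal the O(n·m) brute force.
    """
    qx = np.asarray(query_x, dtype=float)
    qy = np.asarray(query_y, dtype=float)
    tx = np.asarray(target_x, dtype=float)
    ty = np.asarray(target_y, dtype=float)
    if len(qx) == 0:
        raise NeighborError("empty query point set")
    if len(tx) == 0:
        raise NeighborError("empty target point set")
    tree = cKDTree(np.column_stack([tx, ty]))
    d, _ = tree.query(np.column_stack([qx, qy]), k=1)
    return NNResult(
        query=query,
        target=target,
        distances=np.asarray(d, dtype=float),
        n_query=len(qx),
        n_target=len(tx),
    )


def sample_queries(
    n: int,
    k: int,
    seed: int,
    case_ids=None,
) -> np.ndarray:
    """Seeded uniform subsample (without replacement) of query indices.

    With ``case_ids`` given (one per query), sampling is stratified with
    proportional allocation: each case contributes ``k·n_case/n`` queries,
    floors first, remainders to the largest fractional parts (ties broken
    by case order). Returns sorted indices into the query array.
    """
    if k > n:
        raise NeighborError(f"cannot sample {k} from {n} without replacement")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if case_ids is None:
        return np.sort(rng.choice(n, size=k, replace=False))
    case_ids = np.asarray(case_ids)
    if len(case_ids) != n:
        raise NeighborError("case_ids length must match the query population")
    cases, inverse, counts = np.unique(case_ids, return_inverse=True, return_counts=True)
    exact = k * counts / n
    alloc = np.floor(exact).astype(int)
    remainder = k - alloc.sum()
    if remainder > 0:
        frac = exact - alloc
        order = np.lexsort((np.arange(len(cases)), -frac))
        alloc[order[:remainder]] += 1
    chosen = []
    for ci, kc in enumerate(alloc):
        idx = np.flatnonzero(inverse == ci)
        if kc > 0:
            chosen.append(rng.choice(idx, size=kc, replace=False))
    return np.sort(np.concatenate(chosen)) if chosen else np.empty(0, dtype=int)


def compare_nn(dist_a, dist_b, bins: int = 30) -> dict:
    """Medians, rank-sum test and histogram summary for two distance samples."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise NeighborError("both distance samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        u, p = len(a) * len(b) / 2.0, 1.0
    else:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    edges = np.histogram_bin_edges(pooled, bins=bins)
    hist_a, _ = np.histogram(a, bins=edges)
    hist_b, _ = np.histogram(b, bins=edges)
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "u_statistic": float(u),
        "p_value": float(min(p, 1.0)),
        "histogram": {
            "edges": [float(e) for e in edges],
            "counts_a": [int(c) for c in hist_a],
            "counts_b": [int(c) for c in hist_b],
        },
    }
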