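"""Benchmark studies run on the synthetic generators.

These are the fixed study conditions under which the pipeline's behaviour
is characterised: CSR calibration of the cluster score, detection of
Thomas clustering against CSR at equal expected abundance, the monotone
response of the score to cluster tightness, and the linked-vs-independent
bivariate contrasts for co-localization and nearest-neighbour distance.
Problem sizes (1 mm² windows, ~10³ cells per pattern) are desk-scale
choices documented in the methods note.

Every function takes a single integer seed and spawns per-replicate
substreams from it, so results are reproducible and replicates are
independent.
"""

from __future__ import annotations

import numpy as np

from .geometry import Window
from .neighbors import compare_nn, cross_nn_distances
from .quadrat import (
    DEFAULT_HIGH_THRESHOLD,
    DEFAULT_MIN_CELLS,
    high_interaction_fraction,
    morisita_horn,
    tessellate,
)
from .ripley import compare_cluster_scores, default_radii, ripley_k
from .synthetic import SimulationConfig, ThomasParams, simulate_bivariate, simulate_csr, simulate_thomas

#: Shared 1 mm² study window.
STUDY_WINDOW = Window(0.0, 0.0, 1000.0, 1000.0)

#: CSR intensity: 10³ expected cells per window.
CSR_INTENSITY = 1e-3

#: Thomas process matched to the CSR abundance: κ·μ_c = λ.
DETECTION_THOMAS = ThomasParams(
    parent_intensity=5e-5, mean_offspring=20.0, cluster_sd=20.0
)

#: Bivariate contrast: two classes of ~1.5·10³ cells with 20 μm clusters.
BIVARIATE_THOMAS = ThomasParams(
    parent_intensity=5e-5, mean_offspring=30.0, cluster_sd=20.0
)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def csr_calibration(seed: int, n_rep: int = 100) -> dict:
    """Mean K̂ and cluster score over CSR replicates (translation correction).

    Under CSR the estimator should average to πr² and the cluster score
    to 0.
    """
    radii = default_radii(STUDY_WINDOW)
    ks, scores = [], []
    for s in _child_seeds(seed, n_rep):
        pat = simulate_csr(
            SimulationConfig(window=STUDY_WINDOW, seed=s, intensity=CSR_INTENSITY)
        )
        res = ripley_k(pat.x, pat.y, STUDY_WINDOW, radii)
        ks.append(res.k_obs)
        scores.append(res.cluster_score)
    mean_k = np.mean(ks, axis=0)
    band = (radii >= 20.0) & (radii <= 100.0)
    rel_dev = np.abs(mean_k[band] / (np.pi * radii[band] ** 2) - 1.0)
    return {
        "n_rep": n_rep,
        "radii": radii,
        "mean_k": mean_k,
        "max_rel_dev_20_100": float(rel_dev.max()),
        "mean_score": float(np.mean(scores)),
        "scores": np.asarray(scores),
    }


def _thomas_case(seed: int) -> float:
    pat = simulate_thomas(
        SimulationConfig(
            window=STUDY_WINDOW, seed=seed, process_kind="thomas",
            thomas=DETECTION_THOMAS,
        )
    )
    return ripley_k(pat.x, pat.y, STUDY_WINDOW).cluster_score


def _csr_case(seed: int) -> float:
    pat = simulate_csr(
        SimulationConfig(window=STUDY_WINDOW, seed=seed, intensity=CSR_INTENSITY)
    )
    return ripley_k(pat.x, pat.y, STUDY_WINDOW).cluster_score


def detection_suite(seed: int, n_cases: int = 15) -> dict:
    """One case-control suite: cluster scores for Thomas vs CSR cases."""
    seeds = _child_seeds(seed, 2 * n_cases)
    thomas_scores = [_thomas_case(s) for s in seeds[:n_cases]]
    csr_scores = [_csr_case(s) for s in seeds[n_cases:]]
    rep = compare_cluster_scores(thomas_scores, csr_scores)
    rep["thomas_scores"] = thomas_scores
    rep["csr_scores"] = csr_scores
    return rep


def detection_replicates(seed: int, n_suites: int = 100, n_cases: int = 15) -> dict:
    """Repeat the case-control suite; count detections (higher median, p<0.01)."""
    wins = 0
    last = None
    for s in _child_seeds(seed, n_suites):
        rep = detection_suite(s, n_cases)
        wins += rep["median_a"] > rep["median_b"] and rep["p_value"] < 0.01
        last = rep
    return {
        "n_suites": n_suites,
        "n_cases": n_cases,
        "wins": wins,
        "win_rate": wins / n_suites,
        "example_suite": last,
    }


def sigma_response(
    seed: int, sigmas=(10.0, 20.0, 40.0, 80.0), n_rep: int = 50
) -> dict:
    """Mean cluster score per cluster-dispersion σ (tighter ⇒ more clustered).

    Common random numbers: within a replicate every σ level shares one
    parent set (simulated on the window buffered for the largest σ, which
    is conservative for the smaller ones), one offspring-count draw and one
    set of standardized displacements, so only the displacement scale
    changes between levels — the standard variance-reduction design for a
    monotone dose-response comparison.
    """
    window = STUDY_WINDOW
    kappa = DETECTION_THOMAS.parent_intensity
    mu = DETECTION_THOMAS.mean_offspring
    buffer = 4.0 * max(sigmas)
    buffered = window.expand(buffer)
    per_sigma: list[list[float]] = [[] for _ in sigmas]
    for s in _child_seeds(seed, n_rep):
        rng = np.random.default_rng(s)
        n_parents = rng.poisson(kappa * buffered.area)
        px = rng.uniform(buffered.x_min, buffered.x_max, n_parents)
        py = rng.uniform(buffered.y_min, buffered.y_max, n_parents)
        counts = rng.poisson(mu, n_parents)
        z = rng.standard_normal(size=(counts.sum(), 2))
        cx = np.repeat(px, counts)
        cy = np.repeat(py, counts)
        for i, sd in enumerate(sigmas):
            x = cx + sd * z[:, 0]
            y = cy + sd * z[:, 1]
            keep = window.contains(x, y)
            res = ripley_k(x[keep], y[keep], window)
            per_sigma[i].append(res.cluster_score)
    means = [float(np.mean(v)) for v in per_sigma]
    return {"sigmas": list(sigmas), "mean_scores": means, "n_rep": n_rep}


def _bivariate(seed: int, kind: str):
    cfg = SimulationConfig(
        window=STUDY_WINDOW,
        seed=seed,
        process_kind=kind,
        thomas=BIVARIATE_THOMAS,
        label_a="A",
        label_b="B",
        mean_offspring_b=BIVARIATE_THOMAS.mean_offspring,
    )
    pat = simulate_bivariate(cfg)
    return pat.subset("A"), pat.subset("B")


def colocalization_pairs(
    seed: int, n_pairs: int = 100, sides=(100.0, 200.0, 400.0)
) -> dict:
    """Paired linked vs independent simulations: MH, high fraction, NN medians.

    The same per-pair seed drives both processes, so each pair differs only
    in whether the second class shares the first class's cluster parents.
    """
    per_side_mh: dict = {s: {"linked": [], "independent": []} for s in sides}
    high = {"linked": [], "independent": []}
    nn_medians = {"linked": [], "independent": []}
    nn_pooled = {"linked": [], "independent": []}
    for s in _child_seeds(seed, n_pairs):
        for kind, tag in (
            ("linked_bivariate", "linked"),
            ("independent_bivariate", "independent"),
        ):
            a, b = _bivariate(s, kind)
            for side in sides:
                g = tessellate(a.x, a.y, b.x, b.y, STUDY_WINDOW, side)
                per_side_mh[side][tag].append(morisita_horn(g.counts_a, g.counts_b))
                if side == 200.0:
                    high[tag].append(
                        high_interaction_fraction(
                            g, DEFAULT_HIGH_THRESHOLD, DEFAULT_MIN_CELLS
                        )
                    )
            nn = cross_nn_distances(a.x, a.y, b.x, b.y)
            nn_medians[tag].append(nn.median)
            nn_pooled[tag].append(nn.distances)
    out: dict = {"n_pairs": n_pairs, "sides": list(sides)}
    for side in sides:
        lk = np.asarray(per_side_mh[side]["linked"])
        ind = np.asarray(per_side_mh[side]["independent"])
        out[f"mh_wins_{int(side)}"] = int((lk > ind).sum())
        out[f"mh_linked_median_{int(side)}"] = float(np.median(lk))
        out[f"mh_independent_median_{int(side)}"] = float(np.median(ind))
    hl = np.asarray(high["linked"])
    hi = np.asarray(high["independent"])
    out["high_wins"] = int((hl >= hi).sum())
    out["high_linked_median"] = float(np.median(hl))
    out["high_independent_median"] = float(np.median(hi))
    nl = np.asarray(nn_medians["linked"])
    ni = np.asarray(nn_medians["independent"])
    out["nn_wins"] = int((nl < ni).sum())
    out["nn_linked_median"] = float(np.median(nl))
    out["nn_independent_median"] = float(np.median(ni))
    pooled_l = np.concatenate(nn_pooled["linked"])
    pooled_i = np.concatenate(nn_pooled["independent"])
    out["nn_pooled"] = compare_nn(pooled_l, pooled_i)
    return out
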