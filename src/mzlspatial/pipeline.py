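"""End-to-end pipeline: simulate or load cases, gate, and run all spatial stages.

Per case the pipeline runs: gating → subset summary → Ripley's K and
cluster score for the PD1-high and FOXP3+ populations → multiscale quadrat
interaction for PD1hi×Ki67+ and FOXP3+×Ki67+ → cross-type
nearest-neighbour analysis for both query phenotypes (Ki67− queries only,
so a proliferating query never measures distance to itself). Across cases
it compares cluster scores and pooled nearest-neighbour distances between
the two populations, and can compare per-case quantities between case
groups (Kruskal-Wallis for ≥3 groups, Mann-Whitney for 2).

The machine-readable report is deterministic for a fixed config and seed;
every stochastic stage's seed is recorded in it. Raw p-values are reported
without multiplicity adjustment (a note saying so is embedded in the
report); optional Benjamini-Hochberg can be switched on in the config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import gating, neighbors, quadrat, ripley, synthetic
from .geometry import Window
from .io import read_cell_table, write_cell_table, write_json

logger = logging.getLogger("mzlspatial")


class PipelineError(ValueError):
    """Raised for invalid run configurations."""


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Cases are either simulated (``n_cases`` synthetic tissue sections,
    linked or independent proliferation) or loaded from CSV paths.
    """

    seed: int = 0
    n_cases: int = 6
    linked: bool = True
    case_paths: list[str] = field(default_factory=list)
    window: Window | None = None
    n_radii: int = ripley.DEFAULT_N_RADII
    correction: str = "translation"
    quadrat_sides: tuple = quadrat.DEFAULT_SIDES
    min_cells: int = quadrat.DEFAULT_MIN_CELLS
    high_threshold: int = quadrat.DEFAULT_HIGH_THRESHOLD
    nn_sample_ceiling: int = 100_000
    exclude_ki67_queries: bool = True
    adjust_p: bool = False  # optional Benjamini-Hochberg across reported tests
    out_dir: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "window" in raw and raw["window"] is not None:
            raw["window"] = Window.from_dict(raw["window"])
        if "quadrat_sides" in raw:
            raw["quadrat_sides"] = tuple(float(s) for s in raw["quadrat_sides"])
        return cls(**raw)


QUERY_POPULATIONS = ("PD1hi", "FOXP3pos")
TARGET_POPULATION = "Ki67pos"


def analyse_case(
    case_id: str,
    calls: pd.DataFrame,
    window: Window,
    config: RunConfig,
    seed: int,
) -> dict:
    """All spatial stages for one gated case."""
    report: dict = {"case_id": case_id, "seed": seed, "n_cells": int(len(calls))}
    report["subset_summary"] = gating.subset_summary(calls)

    radii = ripley.default_radii(window, config.n_radii)
    report["ripley"] = {}
    for pop in QUERY_POPULATIONS:
        sub = gating.select_population(calls, pop)
        try:
            res = ripley.ripley_k(
                sub["x"], sub["y"], window, radii, correction=config.correction
            )
            report["ripley"][pop] = res.to_dict()
        except ripley.RipleyError as exc:
            report["ripley"][pop] = {"error": str(exc)}
            logger.warning("case %s: K estimation failed for %s: %s", case_id, pop, exc)

    targets = gating.select_population(calls, TARGET_POPULATION)
    report["quadrat"] = {}
    report["nn"] = {}
    for pop in QUERY_POPULATIONS:
        sub = gating.select_population(calls, pop)
        ms = quadrat.multiscale_interaction(
            sub["x"],
            sub["y"],
            targets["x"],
            targets["y"],
            window,
            sides=config.quadrat_sides,
            min_cells=config.min_cells,
            high_threshold=config.high_threshold,
        )
        report["quadrat"][pop] = {
            "pearson_sign_change": ms["pearson_sign_change"],
            "by_side": [r.to_dict() for r in ms["results"]],
        }
        queries = sub[~sub["ki67_pos"]] if config.exclude_ki67_queries else sub
        if len(queries) == 0 or len(targets) == 0:
            report["nn"][pop] = {"error": "empty query or target population"}
            continue
        nn = neighbors.cross_nn_distances(
            queries["x"], queries["y"], targets["x"], targets["y"],
            query=pop, target=TARGET_POPULATION,
        )
        if len(nn.distances) > config.nn_sample_ceiling:
            idx = neighbors.sample_queries(
                len(nn.distances), config.nn_sample_ceiling, seed
            )
            nn.distances = nn.distances[idx]
            nn.sample_size = config.nn_sample_ceiling
            nn.seed = seed
        report["nn"][pop] = nn.to_dict()
        report["nn"][pop]["_distances"] = nn.distances  # stripped before writing
    return report


def _bh_adjust(pvals: list[float]) -> list[float]:
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.clip(adj, 0, 1)
    return [float(v) for v in out]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on every case and the cross-case comparisons.

    Returns the machine-readable report; when ``config.out_dir`` is set,
    also writes ``report.json``, ``summary.md`` and the per-case gated
    tables.
    """
    if config.case_paths:
        cases = []
        for p in config.case_paths:
            table, window = read_cell_table(p)
            cases.append((Path(p).stem, table, window))
    else:
        if config.n_cases < 1:
            raise PipelineError("empty case list: n_cases must be >= 1")
        seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(config.seed).spawn(config.n_cases)
        ]
        cases = []
        for i, s in enumerate(seeds):
            _, table = synthetic.simulate_full_tissue(
                s, window=config.window, linked=config.linked
            )
            w = config.window or synthetic.FULL_TISSUE_DEFAULTS["window"]
            cases.append((f"case_{i + 1:02d}", table, w))

    reference = synthetic.simulate_reference_tonsil(seed=config.seed + 1)
    report: dict = {
        "config": {
            "seed": config.seed,
            "n_cases": len(cases),
            "linked": config.linked,
            "correction": config.correction,
            "quadrat_sides": list(config.quadrat_sides),
            "min_cells": config.min_cells,
            "high_threshold": config.high_threshold,
            "nn_sample_ceiling": config.nn_sample_ceiling,
            "exclude_ki67_queries": config.exclude_ki67_queries,
        },
        "notes": [
            "p-values are reported raw, with no multiplicity adjustment"
            + ("" if not config.adjust_p else " except where marked adjusted"),
        ],
        "cases": [],
    }

    per_case_calls: dict[str, pd.DataFrame] = {}
    gated_tables: dict[str, pd.DataFrame] = {}
    failed: list[str] = []
    for i, (case_id, table, window) in enumerate(cases):
        try:
            gcfg = gating.resolve_thresholds(table, reference=reference)
            calls = gating.gate_cells(table, gcfg)
            case_report = analyse_case(case_id, calls, window, config, seed=config.seed)
            case_report["gating_thresholds"] = {
                k: float(v) for k, v in gcfg.thresholds.items()
            }
            per_case_calls[case_id] = calls
            gated_tables[case_id] = calls
            report["cases"].append(case_report)
            logger.info(
                "case %s: %d cells, %d PD1hi, %d FOXP3+, %d Ki67+",
                case_id,
                len(calls),
                int(calls["pd1_hi"].sum()),
                int(calls["foxp3_pos"].sum()),
                int(calls["ki67_pos"].sum()),
            )
        except (ValueError, KeyError) as exc:
            failed.append(case_id)
            report["cases"].append({"case_id": case_id, "error": str(exc)})
            logger.error("case %s failed: %s", case_id, exc)

    ok = [c for c in report["cases"] if "error" not in c]
    if not ok:
        raise PipelineError("all cases failed; nothing to compare")

    # cross-case comparisons: clustering and NN contrast between populations
    scores = {
        pop: [
            c["ripley"][pop]["cluster_score"]
            for c in ok
            if "cluster_score" in c["ripley"][pop]
        ]
        for pop in QUERY_POPULATIONS
    }
    comparisons: dict = {}
    if all(len(v) > 0 for v in scores.values()):
        comparisons["cluster_scores_pd1hi_vs_foxp3"] = ripley.compare_cluster_scores(
            scores["PD1hi"], scores["FOXP3pos"]
        )
    pooled = {
        pop: np.concatenate(
            [c["nn"][pop]["_distances"] for c in ok if "_distances" in c["nn"][pop]]
        )
        for pop in QUERY_POPULATIONS
    }
    if all(len(v) > 0 for v in pooled.values()):
        comparisons["nn_pd1hi_vs_foxp3"] = neighbors.compare_nn(
            pooled["PD1hi"], pooled["FOXP3pos"]
        )
    if config.adjust_p and comparisons:
        ps = [c["p_value"] for c in comparisons.values()]
        for c, adj in zip(comparisons.values(), _bh_adjust(ps)):
            c["p_value_bh"] = adj
    report["comparisons"] = comparisons
    report["failed_cases"] = failed
    for c in ok:  # strip raw distance arrays from the serialised report
        for pop in QUERY_POPULATIONS:
            c["nn"].get(pop, {}).pop("_distances", None)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(report, out / "report.json")
        for case_id, calls in gated_tables.items():
            write_cell_table(calls, out / f"{case_id}_calls.csv")
        (out / "summary.md").write_text(render_summary(report), encoding="utf-8")
    return report


def group_compare(values_by_group: dict[str, list]) -> dict:
    """Compare a per-case quantity across case groups.

    Two groups dispatch a two-sided Mann-Whitney test, three or more a
    Kruskal-Wallis test; all-identical data give p = 1 by convention.
    """
    if len(values_by_group) < 2:
        raise PipelineError("group comparison needs >= 2 groups")
    for g, v in values_by_group.items():
        if len(v) == 0:
            raise PipelineError(f"group {g!r} has no cases")
    arrays = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    medians = {g: float(np.median(v)) for g, v in values_by_group.items()}
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        test = "mann-whitney" if len(arrays) == 2 else "kruskal-wallis"
        return {"test": test, "p_value": 1.0, "statistic": 0.0, "medians": medians}
    if len(arrays) == 2:
        u, p = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return {
            "test": "mann-whitney",
            "statistic": float(u),
            "p_value": float(min(p, 1.0)),
            "medians": medians,
        }
    h, p = stats.kruskal(*arrays)
    return {
        "test": "kruskal-wallis",
        "statistic": float(h),
        "p_value": float(min(p, 1.0)),
        "medians": medians,
    }


def render_summary(report: dict) -> str:
    """Human-readable Markdown digest of a pipeline report."""
    lines = ["# Spatial pipeline summary", ""]
    lines.append(f"Cases analysed: {len([c for c in report['cases'] if 'error' not in c])}"
                 f" (failed: {len(report.get('failed_cases', []))})")
    lines.append("")
    lines.append("| case | cells | PD1hi score | FOXP3+ score | MH(200) PD1hi | MH(200) FOXP3+ |")
    lines.append("|---|---|---|---|---|---|")
    for c in report["cases"]:
        if "error" in c:
            lines.append(f"| {c['case_id']} | failed: {c['error']} | | | | |")
            continue

        def mh200(pop):
            for r in c["quadrat"][pop]["by_side"]:
                if r["side"] == 200.0:
                    return f"{r['morisita_horn']:.3f}"
            return "-"

        def score(pop):
            d = c["ripley"][pop]
            return f"{d['cluster_score']:.3f}" if "cluster_score" in d else "err"

        lines.append(
            f"| {c['case_id']} | {c['n_cells']} | {score('PD1hi')} | "
            f"{score('FOXP3pos')} | {mh200('PD1hi')} | {mh200('FOXP3pos')} |"
        )
    lines.append("")
    comp = report.get("comparisons", {})
    if "cluster_scores_pd1hi_vs_foxp3" in comp:
        c = comp["cluster_scores_pd1hi_vs_foxp3"]
        lines.append(
            f"Cluster scores: PD1hi median {c['median_a']:.3f} vs "
            f"FOXP3+ median {c['median_b']:.3f} (Mann-Whitney p = {c['p_value']:.3g})"
        )
    if "nn_pd1hi_vs_foxp3" in comp:
        c = comp["nn_pd1hi_vs_foxp3"]
        lines.append(
            f"Nearest Ki67+ distance: PD1hi median {c['median_a']:.1f} um vs "
            f"FOXP3+ median {c['median_b']:.1f} um (Mann-Whitney p = {c['p_value']:.3g})"
        )
    for note in report.get("notes", []):
        lines.append("")
        lines.append(f"_{note}_")
    lines.append("")
    return "\n".join(lines)
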