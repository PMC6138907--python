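#!/usr/bin/env python
"""Cross-type nearest-neighbour analysis: distance to the nearest Ki67+ cell.

For every Ki67− PD1hi and Ki67− FOXP3+ cell the exact distance to the
nearest Ki67+ cell is computed per case, pooled across cases, and the two
query populations are compared with a Mann-Whitney test. Expected finding:
PD1hi cells sit much closer to proliferating cells than FOXP3+ cells do.
"""

from pathlib import Path

import numpy as np

import mzlspatial as mz
from mzlspatial.io import write_json

CALLS = sorted(Path("results/calls").glob("case_*.csv"))


def main() -> None:
    pooled = {"PD1hi": [], "FOXP3pos": []}
    per_case = {}
    for path in CALLS:
        calls, _ = mz.read_cell_table(path)
        ki67 = mz.select_population(calls, "Ki67pos")
        per_case[path.stem] = {}
        for pop in pooled:
            sub = mz.select_population(calls, pop)
            queries = sub[~sub["ki67_pos"]]
            nn = mz.cross_nn_distances(
                queries["x"], queries["y"], ki67["x"], ki67["y"],
                query=pop, target="Ki67pos",
            )
            pooled[pop].append(nn.distances)
            per_case[path.stem][pop] = nn.to_dict()
    dist = {pop: np.concatenate(v) for pop, v in pooled.items()}
    comp = mz.compare_nn(dist["PD1hi"], dist["FOXP3pos"])
    print(
        f"median distance to nearest Ki67+ cell: PD1hi {comp['median_a']:.1f} μm "
        f"vs FOXP3+ {comp['median_b']:.1f} μm (Mann-Whitney p = {comp['p_value']:.3g})"
    )
    write_json({"per_case": per_case, "pooled_comparison": comp}, "results/nn.json")
    print("wrote results/nn.json")


if __name__ == "__main__":
    main()
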