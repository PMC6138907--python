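#!/usr/bin/env python
"""Simulate the six-case synthetic tissue cohort plus the tonsil reference.

Each case is a 1500×1500 μm marked point pattern with four phenotypes
(clustered Tfh analogue, CSR Treg analogue, proliferating B-cells linked to
the Tfh clusters, CD4+ background) and log-normal marker intensities.
Writes one cell table per case and the PD1-high reference population under
results/cases/.
"""

import sys
from pathlib import Path

import numpy as np

import mzlspatial as mz
from mzlspatial.synthetic import FULL_TISSUE_DEFAULTS

SEED = 17
OUT = Path("results/cases")


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else SEED
    window = FULL_TISSUE_DEFAULTS["window"]
    case_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(6)
    ]
    for i, s in enumerate(case_seeds, start=1):
        _, table = mz.simulate_full_tissue(seed=s)
        path = OUT / f"case_{i:02d}.csv"
        mz.write_cell_table(table, path, window=window)
        mix = table["true_label"].value_counts().to_dict()
        print(f"case_{i:02d}: {len(table)} cells {mix}")
    ref = mz.simulate_reference_tonsil(seed=seed + 1)
    mz.write_cell_table(ref, OUT / "tonsil_reference.csv")
    print(f"tonsil reference: {len(ref)} PD1-high cells")
    print(f"wrote {OUT}/case_XX.csv and tonsil_reference.csv (seed {seed})")


if __name__ == "__main__":
    main()
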