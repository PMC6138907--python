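"""Basic plotting helpers for K curves and quadrat scatter plots."""

from __future__ import annotations

import numpy as np


def plot_k_function(result, ax=None):
    """Observed K against the CSR reference πr²."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.radii, result.k_obs, "k-", label="observed K")
    ax.plot(result.radii, result.k_csr, "r--", label="CSR (πr²)")
    ax.set_xlabel("r (μm)")
    ax.set_ylabel("K(r) (μm²)")
    ax.legend()
    ax.set_title(f"cluster score = {result.cluster_score:.3f}")
    return ax


def plot_quadrat_scatter(grid, min_cells: int = 5, ax=None):
    """Per-quadrat bivariate counts; only filter-passing quadrats shown."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = np.maximum(grid.counts_a, grid.counts_b) >= min_cells
    ax.scatter(grid.counts_a[m], grid.counts_b[m], s=12, alpha=0.6)
    ax.set_xlabel("type A count per quadrat")
    ax.set_ylabel("type B count per quadrat")
    ax.set_title(f"quadrat side {grid.side:g} μm")
    return ax
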