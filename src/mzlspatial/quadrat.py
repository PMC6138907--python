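"""Quadrat-based bivariate co-localization measures.

The tissue window is tessellated into non-overlapping equal square
quadrats; cells of two phenotypes are counted per quadrat, and interaction
between the phenotypes is summarised by

* the sample Pearson correlation of the two count vectors over quadrats
  passing a display filter (a quadrat passes when at least one population
  reaches ``min_cells``, default 5),
* the Morisita-Horn overlap index over all retained quadrats,

      MH = 2 Σ x_i y_i / [ (Σx_i²/X² + Σy_i²/Y²) · X · Y ],  X = Σx_i, Y = Σy_i,

  which is 1 for proportional count vectors and 0 for disjoint support, and
* the high-interaction fraction: the share of filter-passing quadrats in
  which both populations strictly exceed a density threshold (default
  > 50 cells each).

Quadrat sides are lengths in μm (100/200/400 μm squares by default);
partial edge strips that cannot hold a complete quadrat are dropped, and
cells falling in them are excluded from the counts. Cell-to-quadrat
assignment uses half-open intervals, so boundary cells are counted exactly
once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import Window

DEFAULT_SIDES = (100.0, 200.0, 400.0)
DEFAULT_MIN_CELLS = 5
DEFAULT_HIGH_THRESHOLD = 50


class QuadratError(ValueError):
    """Raised for unusable tessellations or count vectors."""


@dataclass
class QuadratGrid:
    """Equal square tessellation with per-quadrat counts of two phenotypes."""

    side: float
    n_rows: int
    n_cols: int
    origin: tuple[float, float]
    counts_a: np.ndarray  # flattened row-major, length n_rows*n_cols
    counts_b: np.ndarray
    n_dropped_a: int  # cells of each type falling in dropped edge strips
    n_dropped_b: int

    @property
    def n_quadrats(self) -> int:
        return self.n_rows * self.n_cols

    def table(self) -> "np.ndarray":
        """(row, col, count_a, count_b) per quadrat, row-major."""
        rows, cols = np.divmod(np.arange(self.n_quadrats), self.n_cols)
        return np.column_stack([rows, cols, self.counts_a, self.counts_b])


@dataclass
class InteractionResult:
    """Interaction summary for one phenotype pair at one quadrat side."""

    side: float
    pearson: float
    morisita_horn: float
    high_fraction: float
    n_quadrats_total: int
    n_quadrats_analysed: int
    min_cells: int
    high_threshold: int
    pearson_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "pearson": self.pearson,
            "morisita_horn": self.morisita_horn,
            "high_fraction": self.high_fraction,
            "n_quadrats_total": self.n_quadrats_total,
            "n_quadrats_analysed": self.n_quadrats_analysed,
            "min_cells": self.min_cells,
            "high_threshold": self.high_threshold,
            "pearson_defined": self.pearson_defined,
        }


def _bin_counts(x, y, window: Window, side: float, n_rows: int, n_cols: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    col = np.floor((x - window.x_min) / side).astype(int)
    row = np.floor((y - window.y_min) / side).astype(int)
    keep = (col >= 0) & (col < n_cols) & (row >= 0) & (row < n_rows)
    flat = row[keep] * n_cols + col[keep]
    counts = np.bincount(flat, minlength=n_rows * n_cols).astype(int)
    return counts, int((~keep).sum())


def tessellate(
    xa,
    ya,
    xb,
    yb,
    window: Window,
    side: float,
) -> QuadratGrid:
    """Count two phenotypes over complete side×side quadrats of the window.

    The grid is anchored at the window's lower-left corner; only complete
    quadrats are retained ("equally sized"), so edge strips narrower than
    one side are dropped together with any cells inside them.
    """
    if not side > 0:
        raise QuadratError("quadrat side must be > 0")
    n_cols = int(np.floor(window.width / side + 1e-9))
    n_rows = int(np.floor(window.height / side + 1e-9))
    if n_cols < 1 or n_rows < 1:
        raise QuadratError(
            f"quadrat side {side:g} exceeds the window "
            f"({window.width:g} x {window.height:g})"
        )
    counts_a, dropped_a = _bin_counts(xa, ya, window, side, n_rows, n_cols)
    counts_b, dropped_b = _bin_counts(xb, yb, window, side, n_rows, n_cols)
    return QuadratGrid(
        side=float(side),
        n_rows=n_rows,
        n_cols=n_cols,
        origin=(window.x_min, window.y_min),
        counts_a=counts_a,
        counts_b=counts_b,
        n_dropped_a=dropped_a,
        n_dropped_b=dropped_b,
    )


def morisita_horn(x, y) -> float:
    """Morisita-Horn overlap of two count vectors over the same quadrats."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise QuadratError("count vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise QuadratError("counts must be non-negative")
    X = x.sum()
    Y = y.sum()
    if X <= 0 or Y <= 0:
        raise QuadratError("Morisita-Horn undefined: a count vector sums to zero")
    num = 2.0 * float(np.dot(x, y))
    den = ((np.dot(x, x) / X**2) + (np.dot(y, y) / Y**2)) * X * Y
    return float(num / den)


def _filter_mask(x, y, min_cells: int) -> np.ndarray:
    return np.maximum(x, y) >= min_cells


def pearson_counts(x, y, min_cells: int = DEFAULT_MIN_CELLS) -> float:
    """Pearson correlation of quadrat counts after the display filter.

    A quadrat is analysed when at least one of the two populations reaches
    ``min_cells``. Fewer than three analysed quadrats is an error; a
    constant filtered vector leaves the correlation undefined (nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise QuadratError("count vectors must have equal length")
    m = _filter_mask(x, y, min_cells)
    if m.sum() < 3:
        raise QuadratError(
            f"only {int(m.sum())} quadrats pass the >= {min_cells}-cell filter; "
            "need >= 3 for a correlation"
        )
    xf, yf = x[m], y[m]
    if np.ptp(xf) == 0 or np.ptp(yf) == 0:
        return float("nan")
    return float(stats.pearsonr(xf, yf).statistic)


def high_interaction_fraction(
    grid: QuadratGrid,
    threshold: int = DEFAULT_HIGH_THRESHOLD,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> float:
    """Share of analysed quadrats in which both populations exceed ``threshold``.

    "Analysed" quadrats are those passing the ``min_cells`` display filter;
    the high-interaction rule is strict (> threshold for both counts).
    """
    m = _filter_mask(grid.counts_a, grid.counts_b, min_cells)
    n_analysed = int(m.sum())
    if n_analysed == 0:
        raise QuadratError("no quadrats pass the display filter")
    high = (grid.counts_a[m] > threshold) & (grid.counts_b[m] > threshold)
    return float(high.sum() / n_analysed)


def interaction_at_side(
    xa,
    ya,
    xb,
    yb,
    window: Window,
    side: float,
    min_cells: int = DEFAULT_MIN_CELLS,
    high_threshold: int = DEFAULT_HIGH_THRESHOLD,
) -> InteractionResult:
    """Full interaction summary (Pearson, MH, high fraction) at one side.

    Morisita-Horn is computed over all retained quadrats (it is a
    whole-tessellation index); the display filter applies to Pearson and
    the high-interaction fraction. An under-filled tessellation leaves
    Pearson undefined (nan, flagged) rather than failing the whole summary.
    """
    grid = tessellate(xa, ya, xb, yb, window, side)
    mh = morisita_horn(grid.counts_a, grid.counts_b)
    try:
        pearson = pearson_counts(grid.counts_a, grid.counts_b, min_cells)
        defined = not np.isnan(pearson)
    except QuadratError:
        pearson = float("nan")
        defined = False
    m = _filter_mask(grid.counts_a, grid.counts_b, min_cells)
    if m.sum() > 0:
        high = high_interaction_fraction(grid, high_threshold, min_cells)
    else:
        high = float("nan")
    return InteractionResult(
        side=float(side),
        pearson=pearson,
        morisita_horn=mh,
        high_fraction=high,
        n_quadrats_total=grid.n_quadrats,
        n_quadrats_analysed=int(m.sum()),
        min_cells=min_cells,
        high_threshold=high_threshold,
        pearson_defined=defined,
    )


def multiscale_interaction(
    xa,
    ya,
    xb,
    yb,
    window: Window,
    sides=DEFAULT_SIDES,
    min_cells: int = DEFAULT_MIN_CELLS,
    high_threshold: int = DEFAULT_HIGH_THRESHOLD,
) -> dict:
    """Interaction summaries across quadrat sides, flagging Pearson sign flips."""
    results = [
        interaction_at_side(xa, ya, xb, yb, window, s, min_cells, high_threshold)
        for s in sides
    ]
    signs = {np.sign(r.pearson) for r in results if r.pearson_defined}
    return {
        "results": results,
        "pearson_sign_change": bool(len(signs - {0.0}) > 1),
    }
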