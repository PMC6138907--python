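"""Cell-table CSV readers/writers and JSON result serialisation.

Cell tables are comma-separated UTF-8 text with a mandatory header row.
Mandatory columns: ``cell_id, x, y`` (coordinates in μm, Cartesian, origin
at the window's lower-left, y increasing upward). Either the four marker
intensity columns (CD4, PD1, FOXP3, Ki67) or a ``label`` column must be
present. An optional sidecar header line

    # window: x_min,y_min,x_max,y_max

declares the observation window; without it the bounding rectangle of the
coordinates is used. Floats are written with 9 significant digits, which
round-trips the analysis losslessly at the precision the pipeline uses.

Image-convention input (y increasing downward) can be converted on read
with ``flip_y=True``; all spatial statistics are orientation-invariant, so
this affects only coordinate bookkeeping.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Window
from .synthetic import MARKER_CHANNELS

FLOAT_FORMAT = "%.9g"
WINDOW_PREFIX = "# window:"


class CellTableError(ValueError):
    """Raised for malformed cell-table files."""


def _parse_window_header(path: Path) -> Window | None:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.startswith(WINDOW_PREFIX):
        return None
    parts = first[len(WINDOW_PREFIX):].strip().split(",")
    if len(parts) != 4:
        raise CellTableError(
            f"{path}: malformed window header {first.strip()!r}; "
            "expected '# window: x_min,y_min,x_max,y_max'"
        )
    vals = [float(p) for p in parts]
    return Window(*vals)


def read_cell_table(
    path, flip_y: bool = False
) -> tuple[pd.DataFrame, Window]:
    """Read and validate a cell table; return it with its window.

    Malformed rows (non-numeric coordinates) and duplicate ``cell_id``
    values are rejected with the offending line numbers (1-based, header
    included).
    """
    path = Path(path)
    if not path.exists():
        raise CellTableError(f"no such file: {path}")
    window = _parse_window_header(path)
    header_lines = 1 if window is not None else 0
    table = pd.read_csv(path, skiprows=header_lines, comment=None)
    first_data_line = header_lines + 2  # 1-based line of the first data row

    missing = [c for c in ("cell_id", "x", "y") if c not in table.columns]
    if missing:
        raise CellTableError(f"{path}: missing mandatory columns {missing}")
    has_channels = all(c in table.columns for c in MARKER_CHANNELS)
    has_labels = any(c in table.columns for c in ("label", "phenotype"))
    if not has_channels and not has_labels:
        raise CellTableError(
            f"{path}: need either marker channels {list(MARKER_CHANNELS)} "
            "or a 'label'/'phenotype' column"
        )
    for col in ("x", "y"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & table[col].notna())
        if len(bad):
            lines = [int(i) + first_data_line for i in bad[:5]]
            raise CellTableError(
                f"{path}: non-numeric {col!r} at line(s) {lines}"
            )
        if coerced.isna().any():
            lines = [
                int(i) + first_data_line for i in np.flatnonzero(coerced.isna())[:5]
            ]
            raise CellTableError(f"{path}: missing {col!r} at line(s) {lines}")
        table[col] = coerced.astype(float)
    dup = table["cell_id"].duplicated(keep=False)
    if dup.any():
        lines = [int(i) + first_data_line for i in np.flatnonzero(dup)]
        raise CellTableError(
            f"{path}: duplicate cell_id values at lines {lines[:10]}"
        )
    if has_channels:
        for ch in MARKER_CHANNELS:
            vals = pd.to_numeric(table[ch], errors="coerce")
            if vals.isna().any() or (vals < 0).any():
                raise CellTableError(
                    f"{path}: channel {ch} must be numeric and >= 0"
                )
            table[ch] = vals.astype(float)
    if flip_y:
        y = table["y"].to_numpy()
        top = window.y_max if window is not None else y.max()
        bottom = window.y_min if window is not None else y.min()
        table["y"] = top + bottom - y
    if window is None:
        window = Window.bounding(table["x"], table["y"])
    if not window.contains(table["x"], table["y"]).all():
        raise CellTableError(f"{path}: coordinates outside the declared window")
    return table, window


def write_cell_table(table: pd.DataFrame, path, window: Window | None = None) -> None:
    """Write a cell table as CSV, with an optional window sidecar header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if window is not None:
            fh.write(
                f"{WINDOW_PREFIX} "
                + ",".join(
                    FLOAT_FORMAT % v
                    for v in (window.x_min, window.y_min, window.x_max, window.y_max)
                )
                + "\n"
            )
        table.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if np.isnan(v):
            return None
        if np.isposinf(v):
            return "inf"
        if np.isneginf(v):
            return "-inf"
        return v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj: dict, path) -> None:
    """Deterministic JSON: sorted keys, newline-terminated, NaN → null."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
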