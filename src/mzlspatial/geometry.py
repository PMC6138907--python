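"""Rectangular observation windows for planar cell coordinates (micrometres)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class WindowError(ValueError):
    """Raised for degenerate or inconsistent observation windows."""


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation region, coordinates in μm.

    The window stands in for the scanned tissue section: all cell
    coordinates are expected to lie inside it, and its area enters the
    Ripley's K estimator and the quadrat tessellation.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise WindowError(
                f"degenerate window: [{self.x_min}, {self.x_max}] x "
                f"[{self.y_min}, {self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def shorter_side(self) -> float:
        return min(self.width, self.height)

    def contains(self, x, y) -> np.ndarray:
        """Boolean mask of points inside the closed rectangle."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )

    def expand(self, margin: float) -> "Window":
        """Window grown by ``margin`` on every side (used for buffered simulation)."""
        return Window(
            self.x_min - margin,
            self.y_min - margin,
            self.x_max + margin,
            self.y_max + margin,
        )

    @classmethod
    def bounding(cls, x, y) -> "Window":
        """Bounding rectangle of a point set (the fallback tissue window)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size == 0:
            raise WindowError("cannot bound an empty point set")
        w = cls(float(x.min()), float(y.min()), float(x.max()), float(y.max()))
        return w

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "y_min": self.y_min,
            "x_max": self.x_max,
            "y_max": self.y_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Window":
        return cls(
            float(d["x_min"]), float(d["y_min"]), float(d["x_max"]), float(d["y_max"])
        )
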