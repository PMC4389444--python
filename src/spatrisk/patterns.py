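"""Planar point patterns (case or control locations) with their window."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Window


@dataclass
class PointPattern:
    """A set of planar points observed in a rectangular window.

    Attributes
    ----------
    coords : ndarray, shape (n, 2)
        x, y coordinates in metres.
    window : Window
        Observation window; every point must lie inside it.
    label : str
        Conventionally ``"case"`` or ``"control"``.
    """

    coords: np.ndarray
    window: Window
    label: str = "points"

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n, 2)")
        if self.n < 1:
            raise ValueError("a point pattern needs at least one point")
        inside = self.window.contains(self.coords[:, 0], self.coords[:, 1])
        if not np.all(inside):
            k = int(np.sum(~inside))
            raise ValueError(f"{k} point(s) fall outside the window")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]

    # -- I/O --------------------------------------------------------------

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"x": self.x, "y": self.y})
        df["label"] = self.label
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, window: Window | None = None,
                 label: str | None = None) -> "PointPattern":
        """Read a pattern from a CSV with columns ``x,y`` (optional ``label``).

        If ``label`` is given and the file has a label column, only matching
        rows are kept. Without an explicit window the bounding box of the
        points is used.
        """
        df = pd.read_csv(path)
        if label is not None and "label" in df.columns:
            df = df[df["label"] == label]
        coords = df[["x", "y"]].to_numpy(dtype=float)
        if window is None:
            window = Window(
                coords[:, 0].min(), coords[:, 1].min(),
                coords[:, 0].max(), coords[:, 1].max(),
            )
        return cls(coords, window, label or "points")


def pooled(f: PointPattern, g: PointPattern) -> PointPattern:
    """Concatenate case and control patterns (shared window required)."""
    if f.window != g.window:
        raise ValueError("patterns must share the same window")
    return PointPattern(np.vstack([f.coords, g.coords]), f.window, "pooled")
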