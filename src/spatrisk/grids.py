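"""Planar rasters and rectangular observation windows.

All coordinates are planar metres. Rasters are stored row-major from the
top row; a cell in row ``i``, column ``j`` is the half-open box
``[xmin + j*d, xmin + (j+1)*d) x (ymax - (i+1)*d, ymax - i*d]`` with cell
size ``d``. Values are evaluated and sampled at cell centres.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon, box


@dataclass(frozen=True)
class Window:
    """Rectangular observation window in metres."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("window must have positive width and height")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)

    def as_polygon(self) -> Polygon:
        return box(self.xmin, self.ymin, self.xmax, self.ymax)


class RasterGrid:
    """Regular square-cell raster georeferenced to a :class:`Window`.

    Parameters
    ----------
    values : array_like, shape (nrows, ncols)
        Cell values, row-major from the top row.
    window : Window
        Extent covered by the raster. Must be an integer multiple of
        ``cell_size`` in both directions (to 1e-6 relative).
    cell_size : float
        Side length of the square cells in metres.
    """

    def __init__(self, values, window: Window, cell_size: float):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        nrows = round(window.height / cell_size)
        ncols = round(window.width / cell_size)
        if abs(nrows * cell_size - window.height) > 1e-6 * window.height:
            raise ValueError("window height is not a multiple of cell_size")
        if abs(ncols * cell_size - window.width) > 1e-6 * window.width:
            raise ValueError("window width is not a multiple of cell_size")
        if values.shape != (nrows, ncols):
            raise ValueError(
                f"values shape {values.shape} does not match grid {(nrows, ncols)}"
            )
        self.values = values
        self.window = window
        self.cell_size = float(cell_size)

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    @property
    def x_centers(self) -> np.ndarray:
        w = self.window
        return w.xmin + (np.arange(self.shape[1]) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        """Cell-centre y coordinates, top row first (descending)."""
        w = self.window
        return w.ymax - (np.arange(self.shape[0]) + 0.5) * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of cell-centre coordinates, shape = raster shape."""
        return np.meshgrid(self.x_centers, self.y_centers)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cells containing points (x, y).

        Points on the top/right window edge are folded into the last cell so
        that every point of the closed window has an index.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(self.window.contains(x, y)):
            raise ValueError("points outside the raster window")
        col = np.floor((x - self.window.xmin) / self.cell_size).astype(int)
        row = np.floor((self.window.ymax - y) / self.cell_size).astype(int)
        col = np.clip(col, 0, self.shape[1] - 1)
        row = np.clip(row, 0, self.shape[0] - 1)
        return row, col

    def like(self, values) -> "RasterGrid":
        """New raster with the same georeferencing and different values."""
        return RasterGrid(values, self.window, self.cell_size)

    @classmethod
    def full(cls, window: Window, cell_size: float, fill: float = 0.0) -> "RasterGrid":
        nrows = round(window.height / cell_size)
        ncols = round(window.width / cell_size)
        return cls(np.full((nrows, ncols), fill, dtype=float), window, cell_size)

    # -- interpolation ----------------------------------------------------

    def sample_bilinear(self, x, y) -> np.ndarray:
        """Bilinear interpolation of cell-centre values at points (x, y).

        Outside the centre lattice the value is held constant (edge padding).
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        d = self.cell_size
        fx = (x - (self.window.xmin + 0.5 * d)) / d
        fy = ((self.window.ymax - 0.5 * d) - y) / d
        j0 = np.clip(np.floor(fx).astype(int), 0, self.shape[1] - 2)
        i0 = np.clip(np.floor(fy).astype(int), 0, self.shape[0] - 2)
        tx = np.clip(fx - j0, 0.0, 1.0)
        ty = np.clip(fy - i0, 0.0, 1.0)
        v = self.values
        return (
            v[i0, j0] * (1 - tx) * (1 - ty)
            + v[i0, j0 + 1] * tx * (1 - ty)
            + v[i0 + 1, j0] * (1 - tx) * ty
            + v[i0 + 1, j0 + 1] * tx * ty
        )

    # -- I/O (Esri ASCII grid, plain text) --------------------------------

    def to_ascii(self, path) -> None:
        header = (
            f"ncols {self.shape[1]}\n"
            f"nrows {self.shape[0]}\n"
            f"xllcorner {self.window.xmin!r}\n"
            f"yllcorner {self.window.ymin!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value -9999\n"
        )
        buf = io.StringIO()
        vals = np.where(np.isnan(self.values), -9999.0, self.values)
        np.savetxt(buf, vals, fmt="%.10g")
        with open(path, "w") as fh:
            fh.write(header)
            fh.write(buf.getvalue())

    @classmethod
    def from_ascii(cls, path) -> "RasterGrid":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        nodata = header.get("nodata_value")
        if nodata is not None:
            values = np.where(values == nodata, np.nan, values)
        d = header["cellsize"]
        win = Window(
            header["xllcorner"],
            header["yllcorner"],
            header["xllcorner"] + header["ncols"] * d,
            header["yllcorner"] + header["nrows"] * d,
        )
        return cls(values, win, d)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RasterGrid(shape={self.shape}, cell_size={self.cell_size}, "
            f"window=({self.window.xmin}, {self.window.ymin}, "
            f"{self.window.xmax}, {self.window.ymax}))"
        )
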