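"""Gridded raster container with ESRI ASCII grid text I/O.

All rasters live in a projected planar CRS with coordinates in meters.
``values`` is stored row-major with row 0 at the *top* (north) edge, the
ESRI ASCII grid convention, so ``values[0, 0]`` is the north-west cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """A rectangular grid of cell values on a square-cell lattice.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values; ``nodata`` marks missing cells.
    cell_m : float
        Cell edge length in meters (> 0).
    origin : tuple of float
        ``(x, y)`` of the lower-left (south-west) corner of the grid.
    nodata : float
        Sentinel for missing cells, excluded from all statistics.
    """

    values: np.ndarray
    cell_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = field(default=DEFAULT_NODATA)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_m > 0:
            raise ValueError(f"cell_m must be > 0, got {self.cell_m}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edge."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_m, y0 + self.nrows * self.cell_m)

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        v = self.values
        return ~(np.isnan(v) | (v == self.nodata))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(X, Y)`` of cell-center coordinates, same shape as values."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell_m
        ys = y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_m
        return np.meshgrid(xs, ys)

    def rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing points (x, y)."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_m).astype(int)
        row = (self.nrows - 1 - np.floor((np.asarray(y) - y0) / self.cell_m)).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(np.asarray(values, float), self.cell_m, self.origin, self.nodata)

    def same_grid(self, other: "Raster", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_m - other.cell_m) < tol
            and abs(self.origin[0] - other.origin[0]) < tol
            and abs(self.origin[1] - other.origin[1]) < tol
        )


def write_ascii_grid(raster: Raster, path) -> None:
    """Write a raster as an ESRI ASCII grid (.asc)."""
    v = np.where(raster.mask(), raster.values, raster.nodata)
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cell_m:.6f}\n"
        f"NODATA_value {raster.nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, v, fmt="%.8g")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (.asc) raster."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # optional NODATA line absent
                break
        fh.seek(pos)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    r = Raster(
        values,
        cell_m=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=nodata,
    )
    if r.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {r.shape} does not match header")
    return r
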