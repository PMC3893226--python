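"""Bathymetry grid container and raster I/O.

Depth grids are stored as plain 2D float arrays (metres, positive down) with a
square cell size, the map coordinate of the top-left cell *center*, and a
boolean nodata mask.  Row 0 is the northernmost row (north-up raster
convention).  The interchange format is the ESRI ASCII grid — a widely
supported, diff-able text format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class BathymetryGrid:
    """A rectangular depth raster.

    Parameters
    ----------
    depth : 2D array of water depth in metres, positive down.
    cell_size : edge length of the square cells, metres.
    origin : (easting, northing) of the *center* of the top-left cell, metres.
    nodata_mask : boolean array, True where depth is missing.
    """

    depth: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2 or min(self.depth.shape) < 3:
            raise ValueError("depth grid must be 2D and at least 3x3")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.depth)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.depth.shape:
                raise ValueError("nodata_mask shape mismatch")
        valid = self.depth[~self.nodata_mask]
        if valid.size and not np.all(valid > 0):
            raise ValueError("all unmasked depths must be positive (metres below surface)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(easting, northing) arrays of every cell center."""
        ny, nx = self.shape
        x0, y0 = self.origin
        xs = x0 + np.arange(nx) * self.cell_size
        ys = y0 - np.arange(ny) * self.cell_size
        return np.meshgrid(xs, ys)

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the cell-edge envelope."""
        ny, nx = self.shape
        x0, y0 = self.origin
        h = self.cell_size / 2.0
        return (x0 - h, y0 - (ny - 1) * self.cell_size - h, x0 + (nx - 1) * self.cell_size + h, y0 + h)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the nearest cell center; may fall outside the grid."""
        x0, y0 = self.origin
        col = np.rint((np.asarray(x, dtype=float) - x0) / self.cell_size).astype(int)
        row = np.rint((y0 - np.asarray(y, dtype=float)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.index_of(x, y)
        ny, nx = self.shape
        return (row >= 0) & (row < ny) & (col >= 0) & (col < nx)

    def value_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell depth lookup; points must be in bounds."""
        row, col = self.index_of(x, y)
        return self.depth[row, col]


def write_ascii_grid(array: np.ndarray, cell_size: float, origin: tuple[float, float],
                     path: str | Path, nodata_mask: np.ndarray | None = None) -> None:
    """Write a 2D array as an ESRI ASCII grid (nodata -9999)."""
    arr = np.asarray(array, dtype=float).copy()
    if nodata_mask is not None:
        arr[np.asarray(nodata_mask, dtype=bool)] = NODATA
    arr[~np.isfinite(arr)] = NODATA
    ny, nx = arr.shape
    x0, y0 = origin
    # ESRI header references the lower-left *corner* of the grid.
    xll = x0 - cell_size / 2.0
    yll = y0 - (ny - 1) * cell_size - cell_size / 2.0
    header = (f"ncols {nx}\nnrows {ny}\nxllcorner {xll:.6f}\nyllcorner {yll:.6f}\n"
              f"cellsize {cell_size:.6f}\nNODATA_value {NODATA:.1f}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr.astype(np.float32), fmt="%.6f")


def read_ascii_grid(path: str | Path) -> BathymetryGrid:
    """Read an ESRI ASCII grid into a :class:`BathymetryGrid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
                "cellsize", "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"not an ESRI ASCII grid: missing '{key}' in header of {path}")
    arr = np.loadtxt(lines[n_header:], dtype=float)
    arr = np.atleast_2d(arr)
    ny, nx = int(header["nrows"]), int(header["ncols"])
    if arr.shape != (ny, nx):
        raise ValueError(f"data block shape {arr.shape} does not match header ({ny}, {nx})")
    cs = header["cellsize"]
    nodata = header.get("nodata_value", NODATA)
    mask = arr == nodata
    arr = arr.copy()
    arr[mask] = np.nan
    if "xllcorner" in header:
        x0 = header["xllcorner"] + cs / 2.0
        y0 = header["yllcorner"] + cs / 2.0 + (ny - 1) * cs
    else:
        x0 = header["xllcenter"]
        y0 = header["yllcenter"] + (ny - 1) * cs
    grid = BathymetryGrid.__new__(BathymetryGrid)
    grid.depth = arr
    grid.cell_size = cs
    grid.origin = (x0, y0)
    grid.nodata_mask = mask
    return grid


def write_raster(grid: BathymetryGrid, path: str | Path) -> None:
    write_ascii_grid(grid.depth, grid.cell_size, grid.origin, path, grid.nodata_mask)


def read_raster(path: str | Path) -> BathymetryGrid:
    path = Path(path)
    if path.suffix.lower() not in (".asc", ".txt", ".grd", ""):
        raise ValueError(
            f"unsupported raster format '{path.suffix}': write the layer as an "
            "ESRI ASCII grid (.asc)")
    return read_ascii_grid(path)
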