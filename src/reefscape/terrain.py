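"""Multiscale seafloor-complexity predictors from bathymetry.

Six base surfaces are derived from a depth grid — depth itself, 3x3 standard
deviation of depth, plan (cross-sectional) curvature, Euclidean distance to
the 183 m shelf-edge isobath, Jenness surface-area rugosity, and
slope-of-slope — and each is averaged inside circular windows of 25, 50, 100
and 300 m radius, yielding a 24-layer predictor stack.

Kernel conventions
------------------
* ``focal_sd`` and ``focal_mean`` shrink their window at grid borders (the
  statistic is taken over the cells actually available), so the shallow shelf
  margin is never lost to edge padding.
* Derivative kernels (``slope``, ``plan_curvature``, ``rugosity``,
  ``slope_of_slope``) use nearest-edge padding at the border, the usual DEM
  convention.
* ``focal_sd`` is the population (not sample) standard deviation.
* Curvature sign: convex seafloor (a dome rising toward the surface) is
  positive, concave negative; values are scaled by 100 as is conventional for
  raster curvature products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .grids import BathymetryGrid

logger = logging.getLogger(__name__)

DEFAULT_SURFACES = ("depth", "depth_sd", "plan_curv", "dist_shelf", "rugosity", "slope_of_slope")
DEFAULT_RADII = (25.0, 50.0, 100.0, 300.0)
SHELF_EDGE_DEPTH_M = 183.0
CURVATURE_SCALE = 100.0


def _box_sums(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3x3 neighborhood sum and neighbor count, window shrinking at borders."""
    kernel = np.ones((3, 3))
    s = ndimage.convolve(np.nan_to_num(arr, nan=0.0), kernel, mode="constant", cval=0.0)
    n = ndimage.convolve(np.isfinite(arr).astype(float), kernel, mode="constant", cval=0.0)
    return s, n


def focal_sd(grid: BathymetryGrid) -> np.ndarray:
    """Per-cell population standard deviation of the 3x3 neighborhood."""
    z = np.where(grid.nodata_mask, np.nan, grid.depth)
    s, n = _box_sums(z)
    s2, _ = _box_sums(z * z)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
        var = s2 / n - mean * mean
    out = np.sqrt(np.clip(var, 0.0, None))
    out[grid.nodata_mask] = np.nan
    return out


def _padded(grid: BathymetryGrid) -> np.ndarray:
    """Depth with nearest-edge padding of one cell, nodata filled by nearest."""
    z = grid.depth.copy()
    if grid.nodata_mask.any():
        # fill nodata with nearest valid cell so 3x3 stencils stay defined
        idx = ndimage.distance_transform_edt(grid.nodata_mask, return_distances=False,
                                             return_indices=True)
        z = z[tuple(idx)]
    return np.pad(z, 1, mode="edge")


def slope(grid: BathymetryGrid) -> np.ndarray:
    """Horn 3x3 finite-difference slope, degrees."""
    zp = _padded(grid)
    L = grid.cell_size
    a, b, c = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    d, f = zp[1:-1, :-2], zp[1:-1, 2:]
    g, h, i = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * L)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * L)
    out = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    out[grid.nodata_mask] = np.nan
    return out


def slope_of_slope(grid: BathymetryGrid) -> np.ndarray:
    """Maximum rate of change of slope: the slope of the slope raster."""
    s = slope(grid)
    sgrid = BathymetryGrid.__new__(BathymetryGrid)
    sgrid.depth = np.where(np.isfinite(s), s, np.nan)
    sgrid.cell_size = grid.cell_size
    sgrid.origin = grid.origin
    sgrid.nodata_mask = grid.nodata_mask
    return slope(sgrid)


def plan_curvature(grid: BathymetryGrid) -> np.ndarray:
    """Zevenbergen–Thorne plan curvature (convex positive, scaled by 100).

    The quadratic is fit to the *elevation* surface (negative depth) so the
    sign convention matches topographic intuition: a mound on the seafloor is
    convex and positive.
    """
    zp = -_padded(grid)  # elevation, positive up
    L = grid.cell_size
    z1, z2, z3 = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    z4, z5, z6 = zp[1:-1, :-2], zp[1:-1, 1:-1], zp[1:-1, 2:]
    z7, z8, z9 = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    D = ((z4 + z6) / 2.0 - z5) / L**2
    E = ((z2 + z8) / 2.0 - z5) / L**2
    F = (-z1 + z3 + z7 - z9) / (4.0 * L**2)
    G = (-z4 + z6) / (2.0 * L)
    H = (z2 - z8) / (2.0 * L)
    denom = G * G + H * H
    with np.errstate(invalid="ignore", divide="ignore"):
        # negated so a convex surface (dome) is positive
        curv = -2.0 * (D * H * H + E * G * G - F * G * H) / denom
    curv = np.where(denom == 0.0, 0.0, curv) * CURVATURE_SCALE
    curv[grid.nodata_mask] = np.nan
    return curv


def rugosity(grid: BathymetryGrid) -> np.ndarray:
    """Jenness surface-area / planar-area ratio of each cell (>= 1).

    Eight triangles connect the cell center to the midpoints of the 3D
    segments running to its eight neighbors; their summed Heron area divided
    by the planar cell area is the rugosity.
    """
    zp = _padded(grid)
    L = grid.cell_size
    ny, nx = grid.shape
    center = zp[1:-1, 1:-1]
    # neighbor offsets in ring order (8 neighbors, consecutive pairs adjacent)
    ring = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    half = []
    planar = []
    for dr, dc in ring:
        nb = zp[1 + dr:1 + dr + ny, 1 + dc:1 + dc + nx]
        horiz = L * np.hypot(dr, dc)
        half.append(0.5 * np.sqrt(horiz**2 + (nb - center) ** 2))
        planar.append((dr, dc, nb))
    area = np.zeros(grid.shape)
    for k in range(8):
        k2 = (k + 1) % 8
        dr1, dc1, nb1 = planar[k]
        dr2, dc2, nb2 = planar[k2]
        horiz = L * np.hypot(dr1 - dr2, dc1 - dc2)
        third = 0.5 * np.sqrt(horiz**2 + (nb1 - nb2) ** 2)
        a, b, c = half[k], half[k2], third
        s = (a + b + c) / 2.0
        area += np.sqrt(np.clip(s * (s - a) * (s - b) * (s - c), 0.0, None))
    out = area / (L * L)
    out = np.maximum(out, 1.0)
    out[grid.nodata_mask] = np.nan
    return out


def isobath_cells(grid: BathymetryGrid, level_m: float = SHELF_EDGE_DEPTH_M) -> np.ndarray:
    """Boolean mask of cells on the isobath: depth >= level with a 4-neighbor < level."""
    deep = grid.depth >= level_m
    shallow = np.isfinite(grid.depth) & (grid.depth < level_m)
    near_shallow = ndimage.binary_dilation(shallow, structure=np.array(
        [[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool))
    return deep & near_shallow


def distance_to_isobath(grid: BathymetryGrid, level_m: float = SHELF_EDGE_DEPTH_M) -> np.ndarray:
    """Euclidean distance (km) from each cell center to the nearest isobath cell."""
    iso = isobath_cells(grid, level_m)
    if not iso.any():
        raise ValueError(
            f"no {level_m:g} m isobath crossing in this grid; extend the domain so the "
            "shelf edge is reached")
    dist_m = ndimage.distance_transform_edt(~iso, sampling=grid.cell_size)
    out = dist_m / 1000.0
    out[grid.nodata_mask] = np.nan
    return out


def circular_footprint(radius_m: float, cell_size: float) -> np.ndarray:
    """Boolean kernel of cells whose centers lie within radius of the focal center."""
    r_cells = int(np.floor(radius_m / cell_size))
    offs = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    return (dy * dy + dx * dx) * cell_size**2 <= radius_m**2


def focal_mean(grid: BathymetryGrid, radius_m: float, values: np.ndarray | None = None) -> np.ndarray:
    """Mean over a circular window; nodata excluded, window shrinks at borders.

    ``values`` defaults to the grid's own depth; pass another grid-aligned
    layer to smooth a derived surface.
    """
    if radius_m < grid.cell_size:
        raise ValueError("radius_m must be at least one cell")
    v = grid.depth if values is None else np.asarray(values, dtype=float)
    valid = np.isfinite(v) & ~grid.nodata_mask
    kernel = circular_footprint(radius_m, grid.cell_size).astype(float)
    num = signal.fftconvolve(np.where(valid, v, 0.0), kernel, mode="same")
    den = signal.fftconvolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    return out


_BASE_SURFACES = {
    "depth": lambda g: np.where(g.nodata_mask, np.nan, g.depth),
    "depth_sd": focal_sd,
    "plan_curv": plan_curvature,
    "dist_shelf": distance_to_isobath,
    "rugosity": rugosity,
    "slope_of_slope": slope_of_slope,
    "slope": slope,
}


@dataclass
class PredictorStack:
    """Named, grid-aligned predictor layers ("surface@radius" -> 2D array)."""

    layers: dict[str, np.ndarray]
    grid: BathymetryGrid
    surfaces: tuple[str, ...] = DEFAULT_SURFACES
    radii: tuple[float, ...] = DEFAULT_RADII

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __len__(self) -> int:
        return len(self.layers)


def build_predictor_stack(grid: BathymetryGrid,
                          surfaces: tuple[str, ...] = DEFAULT_SURFACES,
                          radii: tuple[float, ...] = DEFAULT_RADII,
                          isobath_level_m: float = SHELF_EDGE_DEPTH_M,
                          include_native: bool = False) -> PredictorStack:
    """Derive each base surface, then its circular focal mean at each radius.

    The default yields ``len(surfaces) x len(radii)`` = 24 layers named like
    ``"rugosity@300"``.  ``include_native=True`` adds the unsmoothed surfaces
    as ``"name@0"`` layers.
    """
    for r in radii:
        if r < grid.cell_size:
            raise ValueError("all radii must be at least one cell")
    layers: dict[str, np.ndarray] = {}
    for name in surfaces:
        if name not in _BASE_SURFACES:
            raise ValueError(f"unknown surface '{name}'; choose from {sorted(_BASE_SURFACES)}")
        if name == "dist_shelf":
            base = distance_to_isobath(grid, isobath_level_m)
        else:
            base = _BASE_SURFACES[name](grid)
        if include_native:
            layers[f"{name}@0"] = base
        for r in radii:
            layers[f"{name}@{r:g}"] = focal_mean(grid, r, values=base)
    return PredictorStack(layers=layers, grid=grid, surfaces=tuple(surfaces), radii=tuple(radii))


def sample_stack(stack: PredictorStack, points: pd.DataFrame,
                 response_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    """Nearest-cell sampling of every layer at each point.

    ``points`` needs ``x``/``y`` columns; any ``response_columns`` are carried
    through.  Points outside the grid are dropped with a logged count.
    """
    grid = stack.grid
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    inside = grid.contains(x, y)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.warning("sample_stack: dropped %d of %d points outside the grid",
                       n_dropped, len(points))
    kept = points.loc[inside].reset_index(drop=True)
    row, col = grid.index_of(x[inside], y[inside])
    data = {"x": kept["x"].to_numpy(), "y": kept["y"].to_numpy()}
    for name, layer in stack.layers.items():
        data[name] = layer[row, col]
    for rc in response_columns:
        data[rc] = kept[rc].to_numpy()
    out = pd.DataFrame(data)
    out.attrs["n_dropped"] = n_dropped
    # rows whose predictors are all-nodata are unusable for modelling
    pred_cols = list(stack.layers)
    all_nan = out[pred_cols].isna().all(axis=1)
    if all_nan.any():
        logger.warning("sample_stack: dropped %d all-nodata rows", int(all_nan.sum()))
        out = out.loc[~all_nan].reset_index(drop=True)
    return out
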