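"""Terrain and vegetation covariates from gridded elevation / canopy-height data.

Implements the LiDAR-derived covariate stack used to characterise camera
sites: bilinear resampling of a ground DEM to analysis resolution (10 m),
Horn slope/aspect, the vector ruggedness measure (VRM) in a moving window,
vegetation density as the fraction of 1 m canopy cells taller than a height
threshold, and mean covariate extraction within circular buffers.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .raster import Raster

__all__ = [
    "resample_bilinear",
    "slope_aspect",
    "vrm",
    "vegetation_density",
    "buffer_mean",
]


def resample_bilinear(r: Raster, target_cell_m: float) -> Raster:
    """Resample a raster to a coarser resolution by bilinear interpolation.

    Target cell-center values are interpolated from the four surrounding
    source cell centers; nodata neighbours are dropped with weight
    renormalisation, and a target cell whose whole neighbourhood is nodata
    becomes nodata.
    """
    if target_cell_m < r.cell_m:
        raise ValueError("target_cell_m must be >= source cell size")
    nrows_t = max(1, int(round(r.nrows * r.cell_m / target_cell_m)))
    ncols_t = max(1, int(round(r.ncols * r.cell_m / target_cell_m)))

    x0, y0 = r.origin
    xs = x0 + (np.arange(ncols_t) + 0.5) * target_cell_m
    ys = y0 + (nrows_t - np.arange(nrows_t) - 0.5) * target_cell_m
    X, Y = np.meshgrid(xs, ys)

    # fractional source indices in cell-center space
    fc = (X - x0) / r.cell_m - 0.5
    fr = (r.nrows - (Y - y0) / r.cell_m) - 0.5

    c0 = np.clip(np.floor(fc).astype(int), 0, r.ncols - 1)
    r0 = np.clip(np.floor(fr).astype(int), 0, r.nrows - 1)
    c1 = np.clip(c0 + 1, 0, r.ncols - 1)
    r1 = np.clip(r0 + 1, 0, r.nrows - 1)
    tx = np.clip(fc - c0, 0.0, 1.0)
    ty = np.clip(fr - r0, 0.0, 1.0)

    vals = np.where(r.mask(), r.values, np.nan)
    out_num = np.zeros_like(X)
    out_den = np.zeros_like(X)
    for rr, cc, w in (
        (r0, c0, (1 - ty) * (1 - tx)),
        (r0, c1, (1 - ty) * tx),
        (r1, c0, ty * (1 - tx)),
        (r1, c1, ty * tx),
    ):
        v = vals[rr, cc]
        ok = ~np.isnan(v)
        out_num += np.where(ok, w * np.where(ok, v, 0.0), 0.0)
        out_den += np.where(ok, w, 0.0)
    with np.errstate(invalid="ignore"):
        out = np.where(out_den > 0, out_num / np.where(out_den > 0, out_den, 1.0), r.nodata)
    return Raster(out, target_cell_m, r.origin, r.nodata)


def _horn_gradients(dem: Raster) -> tuple[np.ndarray, np.ndarray]:
    """Horn 3x3 finite-difference gradients (east, north), edge-replicated."""
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("DEM must be at least 3x3 for slope computation")
    z = np.where(dem.mask(), dem.values, np.nan)
    p = np.pad(z, 1, mode="edge")
    a, b, c = p[:-2, :-2], p[:-2, 1:-1], p[:-2, 2:]
    d, f = p[1:-1, :-2], p[1:-1, 2:]
    g, h, i = p[2:, :-2], p[2:, 1:-1], p[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * dem.cell_m)
    # row 0 is north, so the northward gradient takes the top row minus bottom
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * dem.cell_m)
    return dzdx, dzdy


def slope_aspect(dem: Raster) -> tuple[Raster, Raster]:
    """Slope and aspect from a DEM using Horn's 3x3 method.

    Returns
    -------
    slope_deg : Raster
        Slope in degrees from horizontal, in [0, 90].
    aspect_deg : Raster
        Uphill direction in degrees clockwise from north; nodata-flagged
        where the surface is locally flat (slope = 0).
    """
    dzdx, dzdy = _horn_gradients(dem)
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    aspect = np.degrees(np.arctan2(dzdx, dzdy)) % 360.0
    aspect = np.where(grad == 0, np.nan, aspect)
    slope = np.where(np.isnan(slope), dem.nodata, slope)
    aspect = np.where(np.isnan(aspect), dem.nodata, aspect)
    return dem.copy_with(slope), dem.copy_with(aspect)


def vrm(dem: Raster, window: int = 3) -> Raster:
    """Vector ruggedness measure in a square moving window.

    Each cell's unit surface-normal is decomposed into (x, y, z) components
    from Horn slope/aspect; the VRM is ``1 - |sum of normals| / n`` over the
    window, 0 for flat or uniformly inclined terrain, approaching 1 for
    maximally rugged terrain. Edge cells use edge-replication padding.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    dzdx, dzdy = _horn_gradients(dem)
    grad = np.hypot(dzdx, dzdy)
    theta = np.arctan(grad)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(grad > 0, dzdx / grad, 0.0)
        uy = np.where(grad > 0, dzdy / grad, 0.0)
    nx = sin_t * ux
    ny = sin_t * uy
    nz = cos_t

    n = window * window
    sums = [
        ndimage.uniform_filter(comp, size=window, mode="nearest") * n
        for comp in (nx, ny, nz)
    ]
    resultant = np.sqrt(sums[0] ** 2 + sums[1] ** 2 + sums[2] ** 2)
    out = 1.0 - resultant / n
    out = np.clip(out, 0.0, 1.0)
    out = np.where(np.isnan(out), dem.nodata, out)
    return dem.copy_with(out)


def vegetation_density(
    chm: Raster, height_threshold: float = 1.0, cell_m: float = 10.0
) -> Raster:
    """Fraction of fine canopy-height cells above a height threshold.

    Aggregates a fine-resolution canopy height model (typically 1 m) into
    coarser analysis cells (typically 10 m); each output cell holds the
    proportion of its constituent valid sub-cells whose canopy height
    exceeds ``height_threshold`` meters.
    """
    factor = cell_m / chm.cell_m
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError("target cell size must be an integer multiple of the CHM cell size")
    factor = int(round(factor))
    if chm.nrows % factor or chm.ncols % factor:
        raise ValueError("CHM grid does not tile evenly into the target cell size")
    valid = chm.mask()
    above = (chm.values > height_threshold) & valid
    nr, nc = chm.nrows // factor, chm.ncols // factor
    above_b = above.reshape(nr, factor, nc, factor).sum(axis=(1, 3))
    valid_b = valid.reshape(nr, factor, nc, factor).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        frac = np.where(valid_b > 0, above_b / np.maximum(valid_b, 1), chm.nodata)
    return Raster(frac, cell_m, chm.origin, chm.nodata)


def buffer_mean(r: Raster, center: tuple[float, float], radius_m: float = 500.0) -> float:
    """Mean of valid cell values whose centers fall within a circular buffer.

    The membership rule is cell-center-in-circle. Raises if the buffer
    contains no valid cell center.
    """
    X, Y = r.cell_centers()
    inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius_m**2
    sel = inside & r.mask()
    if not sel.any():
        raise ValueError(
            f"buffer of radius {radius_m} m at {center} contains no valid raster cells"
        )
    return float(r.values[sel].mean())
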