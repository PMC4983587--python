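"""Predator encounter- and mortality-risk layers from GPS telemetry and kills.

The long-term encounter-risk index follows the isopleth construction
common in lion-telemetry studies: a Gaussian kernel utilization distribution (UD)
with bandwidth 0.6 x the bivariate reference bandwidth h_ref, consecutive
10% isopleths A_10 ... A_100, and a per-area presence probability of
0.1 / (A_i - A_{i-10}) inside each annulus (10% of fixes fall between
consecutive isopleths). Mortality risk is the proportion of investigated
kills falling inside a site's buffer; short-term risk is the proportion of
(daily-subsampled) fixes inside the buffer during a camera's active window.
Feeding clusters are detected as runs of consecutive fixes staying within
100 m of their running centroid for more than two locations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import Raster

__all__ = [
    "GpsTrack",
    "UD",
    "Cluster",
    "RiskSummary",
    "href",
    "kernel_ud",
    "encounter_risk_surface",
    "combined_encounter_risk",
    "subsample_daily",
    "detect_clusters",
    "kill_probability",
    "kill_species_proportions",
    "shortterm_risk",
]

logger = logging.getLogger("riskscape")

ISOPLETH_LEVELS = tuple(range(10, 101, 10))


@dataclass
class GpsTrack:
    """Time-ordered GPS fixes for one animal (projected coordinates, meters)."""

    animal_id: str
    fixes: pd.DataFrame  # columns: timestamp, x, y

    def __post_init__(self) -> None:
        required = {"timestamp", "x", "y"}
        if not required.issubset(self.fixes.columns):
            raise ValueError(f"fixes must have columns {sorted(required)}")
        ts = self.fixes["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError(f"track {self.animal_id}: timestamps must be increasing")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def points(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy(float)


@dataclass
class UD:
    """Kernel utilization distribution on a grid.

    ``density`` holds probability *mass per cell* (sums to 1);
    ``isopleth_areas`` maps isopleth level (10, 20, ..., 100) to the area in
    km^2 of the smallest cell set containing that percentage of the mass.
    """

    density: Raster
    h: float
    isopleth_areas: dict[int, float] = field(default_factory=dict)


@dataclass
class Cluster:
    """A run of consecutive stationary fixes flagged as a potential kill site."""

    animal_id: str
    indices: tuple[int, int]  # [first, last] fix index, inclusive
    centroid: tuple[float, float]
    start: pd.Timestamp
    end: pd.Timestamp
    n_fixes: int
    kill: tuple[str, str] | None = None  # (species, source in {stomach, carcass})


@dataclass
class RiskSummary:
    site_id: str
    encounter_long: float
    encounter_short: float | None
    p_kill: float


# ---------------------------------------------------------------------------
# kernel UD and encounter risk
# ---------------------------------------------------------------------------

def href(points: np.ndarray) -> float:
    """Bivariate reference kernel bandwidth.

    h_ref = sqrt((var_x + var_y) / 2) * n^(-1/6), with sample variances
    (ddof = 1). Callers multiply by a smoothing factor (0.6 by default in
    this pipeline) to counteract over-smoothing of clumped fixes.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    if n < 5:
        raise ValueError("h_ref requires at least 5 points")
    var_x = pts[:, 0].var(ddof=1)
    var_y = pts[:, 1].var(ddof=1)
    if var_x + var_y == 0:
        raise ValueError("degenerate point set: all points identical")
    return float(np.sqrt((var_x + var_y) / 2.0) * n ** (-1.0 / 6.0))


def kernel_ud(points: np.ndarray, h: float, grid: Raster) -> UD:
    """Gaussian kernel UD on a raster grid, with 10% isopleth areas.

    Mass is normalised to 1 over the grid; if the grid does not cover the
    points out to 3h a warning is emitted (the renormalisation then inflates
    in-grid density slightly). Isopleth areas are computed by sorting cell
    masses in descending order and accumulating — A_i is the area of the
    smallest cell set holding i% of the mass.
    """
    pts = np.asarray(points, float)
    if not h > 0:
        raise ValueError("bandwidth h must be > 0")
    xmin, ymin, xmax, ymax = grid.extent
    if (
        pts[:, 0].min() - 3 * h < xmin
        or pts[:, 0].max() + 3 * h > xmax
        or pts[:, 1].min() - 3 * h < ymin
        or pts[:, 1].max() + 3 * h > ymax
    ):
        warnings.warn("UD grid does not cover points +/- 3h; mass renormalized", stacklevel=2)

    X, Y = grid.cell_centers()
    xc = X.ravel()
    yc = Y.ravel()
    dens = np.zeros(xc.size)
    inv2h2 = 1.0 / (2.0 * h * h)
    # chunk over fixes to bound the (n_points x n_cells) working array
    chunk = max(1, int(4e6 // max(xc.size, 1)) or 1)
    for s in range(0, len(pts), chunk):
        p = pts[s : s + chunk]
        d2 = (xc[None, :] - p[:, 0, None]) ** 2 + (yc[None, :] - p[:, 1, None]) ** 2
        dens += np.exp(-d2 * inv2h2).sum(axis=0)
    mass = dens * grid.cell_m**2 / (2 * np.pi * h * h * len(pts))
    total = mass.sum()
    if total <= 0:
        raise ValueError("kernel UD has zero mass on the grid")
    mass /= total

    cell_km2 = (grid.cell_m / 1000.0) ** 2
    order = np.argsort(mass)[::-1]
    cum = np.cumsum(mass[order])
    areas: dict[int, float] = {}
    for lev in ISOPLETH_LEVELS:
        ncells = int(np.searchsorted(cum, lev / 100.0 - 1e-12) + 1)
        ncells = min(ncells, int((mass > 0).sum()))
        areas[lev] = ncells * cell_km2

    density = grid.copy_with(mass.reshape(grid.shape))
    return UD(density=density, h=h, isopleth_areas=areas)


def encounter_risk_surface(ud: UD) -> Raster:
    """Per-area predator presence probability from UD isopleth annuli.

    Every cell in the annulus between isopleths i-10 and i receives
    0.1 / (A_i - A_{i-10}) (probability per km^2); the innermost region gets
    0.1 / A_10 and cells outside A_100 get 0. Zero-area annuli (coarse
    grids) are merged with the annulus inside them. By construction the
    surface integrates to 1 over the study area.
    """
    grid = ud.density
    mass = grid.values.ravel()
    cell_km2 = (grid.cell_m / 1000.0) ** 2
    order = np.argsort(mass)[::-1]

    counts = {0: 0}
    for lev in ISOPLETH_LEVELS:
        counts[lev] = int(round(ud.isopleth_areas[lev] / cell_km2))

    out = np.zeros(mass.size)
    prev_lev = 0
    lev_iter = iter(ISOPLETH_LEVELS)
    for lev in lev_iter:
        lo, hi = counts[prev_lev], counts[lev]
        frac = (lev - prev_lev) / 100.0
        while hi == lo:  # merge empty annulus outward
            nxt = next(lev_iter, None)
            if nxt is None:
                break
            logger.warning("zero-area annulus at %d%% merged with next level", lev)
            lev = nxt
            hi = counts[lev]
            frac = (lev - prev_lev) / 100.0
        if hi > lo:
            area = (hi - lo) * cell_km2
            out[order[lo:hi]] = frac / area
        prev_lev = lev
    return grid.copy_with(out.reshape(grid.shape))


def combined_encounter_risk(
    tracks: list[GpsTrack],
    grid: Raster,
    href_multiplier: float = 0.6,
    weights: list[float] | None = None,
) -> tuple[Raster, list[UD]]:
    """Population-level encounter risk from several collared animals.

    Each animal's risk surface is computed from its own UD (bandwidth
    ``href_multiplier * h_ref``) and the surfaces are averaged, weighted by
    each animal's share of the total fixes unless explicit weights are
    given. The combined surface still integrates to 1 over the study area.
    """
    if not tracks:
        raise ValueError("at least one track required")
    if weights is None:
        n_total = sum(len(t) for t in tracks)
        weights = [len(t) / n_total for t in tracks]
    elif len(weights) != len(tracks):
        raise ValueError("weights must match tracks")
    w = np.asarray(weights, float)
    w = w / w.sum()

    uds: list[UD] = []
    combined = np.zeros(grid.shape)
    for track, wi in zip(tracks, w):
        h = href_multiplier * href(track.points)
        ud = kernel_ud(track.points, h, grid)
        uds.append(ud)
        combined += wi * encounter_risk_surface(ud).values
    return grid.copy_with(combined), uds


# ---------------------------------------------------------------------------
# subsampling, clusters, kill probability
# ---------------------------------------------------------------------------

def subsample_daily(track: GpsTrack, k: int = 3, target_hours: list[float] | None = None) -> GpsTrack:
    """Thin a track to k fixes per calendar day.

    Per day, keep the fixes nearest to k evenly spaced target times
    (default 06:00, 14:00, 22:00 for k = 3); days with fewer than k fixes
    keep all their fixes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if target_hours is None:
        step = 24.0 / k
        target_hours = [(6.0 + i * step) % 24.0 for i in range(k)]
    fx = track.fixes.reset_index(drop=True)
    hours = (
        fx["timestamp"].dt.hour
        + fx["timestamp"].dt.minute / 60.0
        + fx["timestamp"].dt.second / 3600.0
    )
    keep: list[int] = []
    for _, day_idx in fx.groupby(fx["timestamp"].dt.date).groups.items():
        day_idx = list(day_idx)
        if len(day_idx) <= k:
            keep.extend(day_idx)
            continue
        chosen: set[int] = set()
        for th in target_hours:
            best = min(
                (i for i in day_idx if i not in chosen),
                key=lambda i: abs(hours[i] - th),
            )
            chosen.add(best)
        keep.extend(sorted(chosen))
    out = fx.loc[sorted(keep)].reset_index(drop=True)
    return GpsTrack(track.animal_id, out)


def detect_clusters(
    track: GpsTrack, radius_m: float = 100.0, min_fixes: int = 3
) -> list[Cluster]:
    """Detect stationary GPS clusters (potential kill sites).

    Greedy sequential scan: open a candidate at each fix and extend it while
    the next consecutive fix lies strictly within ``radius_m`` of the
    running centroid (updated after each addition). Maximal runs with at
    least ``min_fixes`` members are emitted; emitted runs do not overlap.
    """
    fx = track.fixes.reset_index(drop=True)
    pts = fx[["x", "y"]].to_numpy(float)
    ts = fx["timestamp"]
    n = len(pts)
    clusters: list[Cluster] = []
    i = 0
    while i < n:
        cx, cy = pts[i]
        count = 1
        j = i + 1
        while j < n:
            dx = pts[j, 0] - cx
            dy = pts[j, 1] - cy
            if np.hypot(dx, dy) < radius_m:
                count += 1
                cx += dx / count
                cy += dy / count
                j += 1
            else:
                break
        if count >= min_fixes:
            clusters.append(
                Cluster(
                    animal_id=track.animal_id,
                    indices=(i, j - 1),
                    centroid=(float(cx), float(cy)),
                    start=ts.iloc[i],
                    end=ts.iloc[j - 1],
                    n_fixes=count,
                )
            )
            i = j
        else:
            i += 1
    return clusters


def kill_probability(
    kills: np.ndarray,
    sites: pd.DataFrame,
    radius_m: float = 500.0,
) -> pd.Series:
    """Proportion of kills falling within each site's circular buffer.

    ``kills`` is an (n, 2) array of kill coordinates; ``sites`` has columns
    site_id, x, y. The denominator is the total number of kills passed in
    (the caller chooses the species subset, e.g. medium-to-large
    herbivores); a kill inside several overlapping buffers counts toward
    each of them.
    """
    kills = np.atleast_2d(np.asarray(kills, float))
    if kills.size == 0:
        raise ValueError("empty kill list")
    out = {}
    for _, row in sites.iterrows():
        d2 = (kills[:, 0] - row["x"]) ** 2 + (kills[:, 1] - row["y"]) ** 2
        out[row["site_id"]] = float((d2 <= radius_m**2).sum() / len(kills))
    return pd.Series(out, name="p_kill")


def kill_species_proportions(kills: pd.DataFrame) -> pd.Series:
    """Proportion of kills per prey species (column ``species``)."""
    if len(kills) == 0:
        raise ValueError("empty kill table")
    return kills["species"].value_counts(normalize=True).rename("proportion")


def shortterm_risk(
    track: GpsTrack,
    site: tuple[float, float],
    window: tuple[pd.Timestamp, pd.Timestamp],
    radius_m: float = 500.0,
) -> float | None:
    """Proportion of in-window fixes inside a site's buffer.

    The track should already be daily-subsampled. Returns None (missing
    flag) when no fixes fall inside the window, mirroring the exclusion of
    sites whose survey window did not overlap the collar record.
    """
    start, end = window
    fx = track.fixes
    in_win = (fx["timestamp"] >= start) & (fx["timestamp"] <= end)
    denom = int(in_win.sum())
    if denom == 0:
        return None
    sub = fx.loc[in_win]
    d2 = (sub["x"] - site[0]) ** 2 + (sub["y"] - site[1]) ** 2
    return float((d2 <= radius_m**2).sum() / denom)
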