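"""Seeded synthetic inputs with known ground truth for the whole pipeline.

Emulates the statistical structure the analysis assumes: a square
semi-arid landscape with open plains grading into rugged, thicket-covered
hills; a small collared predator population with clumped space use (so 10%
UD isopleths are informative) and stationary feeding clusters embedded in
the tracks; camera deployments on a sampling grid; and per-site detection
counts drawn from a log-linear Poisson model with a per-camera Normal
random intercept and a day/night effect. Photo timestamps are scattered so
that re-filtering with the 30-min independence rule recovers the
generating event counts exactly (photos within an event <= 5 min apart,
events >= 45 min apart).

Everything is driven by integer seeds: the same seed gives bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .glmm import ModelSpec, build_design
from .predation import GpsTrack
from .raster import Raster

__all__ = [
    "LandscapeConfig",
    "TruthModel",
    "SurveyData",
    "gen_landscape",
    "gen_lion_tracks",
    "gen_camera_survey",
    "simulate_counts",
    "STUDY_LAT",
    "STUDY_LON",
    "STUDY_TZ",
]

# default study setting: southern-hemisphere subtropics, UTC+2 clock time
STUDY_LAT = -33.4
STUDY_LON = 25.8
STUDY_TZ = "Etc/GMT-2"  # fixed UTC+02:00


@dataclass
class LandscapeConfig:
    """Geometry and texture of the synthetic study landscape.

    ``veg_gradient`` is the fraction of the area that is open plains (the
    rest is dense thicket, canopy 3-5 m tall); ``ruggedness_scale`` is the
    elevation-noise amplitude in meters (0 gives perfectly flat terrain and
    hence zero VRM everywhere).
    """

    extent_m: float = 2000.0
    cell_m: float = 10.0
    chm_cell_m: float = 1.0
    veg_gradient: float = 0.5
    ruggedness_scale: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_m <= 0 or self.cell_m <= 0 or self.chm_cell_m <= 0:
            raise ValueError("extent and cell sizes must be positive")
        if not 0.0 <= self.veg_gradient <= 1.0:
            raise ValueError("veg_gradient must be in [0, 1]")
        if self.ruggedness_scale < 0:
            raise ValueError("ruggedness_scale must be non-negative")


def _smooth_noise(rng, shape, sigmas, weights):
    """Sum of Gaussian-filtered white-noise fields, normalised to unit SD."""
    out = np.zeros(shape)
    for s, w in zip(sigmas, weights):
        out += w * ndimage.gaussian_filter(rng.standard_normal(shape), s, mode="wrap")
    sd = out.std()
    return out / sd if sd > 0 else out


def gen_landscape(config: LandscapeConfig) -> tuple[Raster, Raster]:
    """Generate a ground DEM and a fine-resolution canopy height model.

    The DEM is low-frequency noise at two length scales whose amplitude
    ramps up northward (plains in the south, hills in the north); the CHM
    marks a dense-thicket region with canopy 3-5 m and an open region of
    low scattered cover, split by a smoothed threshold so that a
    ``veg_gradient`` fraction of the area is open.
    """
    rng = np.random.default_rng(config.seed)
    n_dem = max(3, int(round(config.extent_m / config.cell_m)))
    n_chm = max(1, int(round(config.extent_m / config.chm_cell_m)))

    yfrac = np.linspace(1.0, 0.0, n_dem)[:, None]  # row 0 = north
    relief = _smooth_noise(rng, (n_dem, n_dem), sigmas=(n_dem / 8, n_dem / 30), weights=(0.75, 0.25))
    dem_vals = config.ruggedness_scale * relief * (0.35 + 0.65 * yfrac)
    dem = Raster(dem_vals, config.cell_m, (0.0, 0.0))

    # open/dense split from a smooth field biased open toward the south
    pattern = _smooth_noise(rng, (n_chm, n_chm), sigmas=(n_chm / 20,), weights=(1.0,))
    pattern = pattern + 1.2 * np.linspace(1.0, -1.0, n_chm)[:, None]  # south opener
    thresh = np.quantile(pattern, config.veg_gradient)
    dense = pattern > thresh
    heights = np.where(
        dense,
        rng.uniform(0.5, 5.0, (n_chm, n_chm)),  # thicket, mostly 3-5 m crowns
        rng.uniform(0.0, 1.2, (n_chm, n_chm)),  # open plain, scattered low cover
    )
    heights = np.where(dense & (heights > 2.0), rng.uniform(3.0, 5.0, (n_chm, n_chm)), heights)
    chm = Raster(heights, config.chm_cell_m, (0.0, 0.0))
    return dem, chm


def gen_lion_tracks(
    dem: Raster,
    n_lions: int = 2,
    fixes_per_day: int = 5,
    n_days: int = 60,
    cluster_spec: list[tuple[tuple[float, float], int]] | None = None,
    seed: int = 0,
    step_sd: float = 250.0,
    min_step_m: float = 0.0,
    start: str = "2013-01-01 00:00:00",
) -> list[GpsTrack]:
    """Simulate collared-predator tracks with embedded feeding clusters.

    Each animal performs a biased random walk pulled toward 1-3 activity
    centers (giving a clumped utilization distribution). Requested clusters
    ``(center, n_fixes)`` are assigned round-robin across animals and
    overwrite ``n_fixes`` consecutive fixes with points within ~30 m of the
    cluster center, a constructed positive control for cluster detection.

    ``min_step_m`` > 0 enforces a floor on every travel step (directed
    movement between resting sites); setting it above twice the cluster
    radius guarantees the walk itself contains no stationary runs, so any
    detected cluster must be a planted one.
    """
    if n_lions < 1:
        raise ValueError("n_lions must be >= 1")
    xmin, ymin, xmax, ymax = dem.extent
    cluster_spec = list(cluster_spec or [])
    for (cx, cy), _ in cluster_spec:
        if not (xmin <= cx <= xmax and ymin <= cy <= ymax):
            raise ValueError(f"cluster center ({cx}, {cy}) outside landscape extent")

    rng = np.random.default_rng(seed)
    n_fix = fixes_per_day * n_days
    t0 = pd.Timestamp(start, tz=STUDY_TZ)
    hours = (np.arange(n_fix) % fixes_per_day) * (24.0 / fixes_per_day) + 12.0 / fixes_per_day
    days = np.arange(n_fix) // fixes_per_day
    times = t0 + pd.to_timedelta(days, unit="D") + pd.to_timedelta(hours, unit="h")

    def _reflect(v, lo, hi):
        # reflective boundaries: clipping would pile fixes into corners and
        # fabricate stationary clusters at the fence
        span2 = 2 * (hi - lo)
        v = (v - lo) % span2
        return lo + np.where(v > hi - lo, span2 - v, v)

    tracks: list[GpsTrack] = []
    for li in range(n_lions):
        n_centers = int(rng.integers(1, 4))
        span = np.array([xmax - xmin, ymax - ymin])
        centers = np.array([xmin, ymin]) + (0.15 + 0.7 * rng.random((n_centers, 2))) * span
        pos = centers[0].astype(float).copy()
        pts = np.empty((n_fix, 2))
        c_idx = 0
        for t in range(n_fix):
            if rng.random() < 0.02:  # occasional shift of activity center
                c_idx = int(rng.integers(n_centers))
            pull = 0.15 * (centers[c_idx] - pos)
            for _ in range(50):
                delta = pull + rng.normal(0.0, step_sd, 2)
                norm = np.hypot(*delta)
                if min_step_m > 0 and norm < min_step_m:
                    delta = delta * (min_step_m / norm) if norm > 0 else np.array([min_step_m, 0.0])
                cand = pos + delta
                if xmin <= cand[0] <= xmax and ymin <= cand[1] <= ymax:
                    pos = cand
                    break
            else:
                pos = pos + pull  # cornered: fall back to the center pull
                pos[0] = _reflect(pos[0], xmin, xmax)
                pos[1] = _reflect(pos[1], ymin, ymax)
            pts[t] = pos
        tracks.append(
            GpsTrack(
                f"lion_{li}",
                pd.DataFrame({"timestamp": times, "x": pts[:, 0], "y": pts[:, 1]}),
            )
        )

    next_free = {li: 0 for li in range(n_lions)}
    for ci, ((cx, cy), nf) in enumerate(cluster_spec):
        if nf < 1:
            raise ValueError("cluster n_fixes must be >= 1")
        li = ci % n_lions
        fx = tracks[li].fixes
        s = next_free[li] + int(rng.integers(2, 6))
        if s + nf > len(fx):
            raise ValueError("too many clusters for the track length")
        next_free[li] = s + nf + 1  # leave a gap so planted clusters stay distinct
        jitter = rng.normal(0.0, 12.0, (nf, 2)).clip(-30.0, 30.0)
        fx.loc[s : s + nf - 1, "x"] = cx + jitter[:, 0]
        fx.loc[s : s + nf - 1, "y"] = cy + jitter[:, 1]
    return tracks


@dataclass
class TruthModel:
    """Generating parameters for synthetic camera counts.

    ``beta`` holds named fixed-effect coefficients on the log scale (keys
    from T, V, R, E, K and their two-way interactions; covariates enter
    already rescaled); ``baseline_rate`` is the expected number of groups
    per 100 days with all covariates at zero (night stratum).
    """

    beta: dict[str, float] = field(default_factory=dict)
    sigma_camera: float = 0.5
    baseline_rate: float = 20.0

    def __post_init__(self) -> None:
        if self.sigma_camera < 0:
            raise ValueError("sigma_camera must be >= 0")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")

    @property
    def spec(self) -> ModelSpec:
        mains = [t for t in self.beta if ":" not in t]
        inters = [t for t in self.beta if ":" in t]
        return ModelSpec("truth", tuple(mains) + tuple(inters))


def simulate_counts(rows: pd.DataFrame, truth: TruthModel, rng) -> pd.DataFrame:
    """Draw Poisson counts for observation rows under a truth model.

    ``rows`` carries site_id, diel, effort_days and covariates V, R, E, K;
    the returned copy adds ``mu`` (the conditional Poisson mean, including
    the site's random intercept) and integer ``count``.
    """
    X, names = build_design(rows, truth.spec, reference="night")
    beta = np.array([np.log(truth.baseline_rate)] + [truth.beta[t] for t in names[1:]])
    sites, site_idx = np.unique(rows["site_id"], return_inverse=True)
    b = rng.normal(0.0, truth.sigma_camera, len(sites)) if truth.sigma_camera > 0 else np.zeros(len(sites))
    eta = np.log(rows["effort_days"].to_numpy(float) / 100.0) + X @ beta + b[site_idx]
    mu = np.exp(eta)
    out = rows.copy()
    out["mu"] = mu
    out["count"] = rng.poisson(mu)
    out["b_site"] = b[site_idx]
    return out


@dataclass
class SurveyData:
    """A simulated camera survey: deployments, photos, and the truth rows."""

    deployments: pd.DataFrame
    photos: pd.DataFrame
    truth_rows: pd.DataFrame

    def __iter__(self):  # allow (deployments, photos) unpacking
        return iter((self.deployments, self.photos))


# diel-safe event windows (clock time UTC+2 at the study longitude):
# 09:00-15:00 is daylight and 20:00-03:30 is night on every day of the year
_DAY_SLOT_H0, _N_DAY_SLOTS = 9.0, 8
_NIGHT_SLOT_H0, _N_NIGHT_SLOTS = 20.0, 10
_SLOT_MIN = 45.0


def _event_times(rng, n_events: int, n_days: int, diel: str, t0: pd.Timestamp):
    if diel == "day":
        h0, per_day = _DAY_SLOT_H0, _N_DAY_SLOTS
    else:
        h0, per_day = _NIGHT_SLOT_H0, _N_NIGHT_SLOTS
    slots = n_days * per_day
    if n_events > slots:
        raise ValueError("more events than available independent time slots")
    chosen = rng.choice(slots, size=n_events, replace=False)
    chosen.sort()
    day = chosen // per_day
    k = chosen % per_day
    return t0 + pd.to_timedelta(day, unit="D") + pd.to_timedelta(
        h0 * 60 + k * _SLOT_MIN, unit="m"
    )


def gen_camera_survey(
    dem: Raster,
    chm: Raster | None,
    risk: Raster | None,
    truth: TruthModel,
    n_sites: int = 63,
    days_per_site: int = 100,
    seed: int = 0,
    species: str = "herbivore",
    pkill: pd.Series | None = None,
    start: str = "2014-01-01 00:00:00",
    buffer_radius_m: float = 500.0,
) -> SurveyData:
    """Simulate a camera-trap survey over a synthetic landscape.

    Sites are placed on a regular grid; per site the covariates V
    (vegetation density), R (VRM x 10^3) and E (encounter risk x 10^1) are
    extracted as 500 m buffer means from the supplied rasters (absent
    rasters contribute zeros), K comes from ``pkill`` (x 10^1) when given.
    Counts per site and diel stratum are Poisson with log-mean
    log(effort/100) + X beta + b_site, and each event is realised as 1-3
    photos <= 5 min apart, with events >= 45 min apart inside diel-safe
    clock windows, so the 30-min independence filter recovers the
    generating event counts exactly.
    """
    from .terrain import buffer_mean, vegetation_density, vrm

    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = dem.extent
    ncol = int(np.ceil(np.sqrt(n_sites)))
    nrow = int(np.ceil(n_sites / ncol))
    margin = min(buffer_radius_m / 2, (xmax - xmin) / 10)
    xs = np.linspace(xmin + margin, xmax - margin, ncol)
    ys = np.linspace(ymin + margin, ymax - margin, nrow)
    coords = [(x, y) for y in ys for x in xs][:n_sites]

    veg_r = vegetation_density(chm) if chm is not None else None
    vrm_r = vrm(dem)

    t0 = pd.Timestamp(start, tz=STUDY_TZ)
    deployments = pd.DataFrame(
        {
            "site_id": [f"site_{i:03d}" for i in range(n_sites)],
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
            "start": t0,
            "end": t0 + pd.Timedelta(days=days_per_site),
            "lat": STUDY_LAT,
            "lon": STUDY_LON,
        }
    )

    rows = []
    for _, d in deployments.iterrows():
        center = (d["x"], d["y"])
        V = buffer_mean(veg_r, center, buffer_radius_m) if veg_r is not None else 0.0
        R = buffer_mean(vrm_r, center, buffer_radius_m) * 1e3
        E = buffer_mean(risk, center, buffer_radius_m) * 1e1 if risk is not None else 0.0
        K = float(pkill.get(d["site_id"], 0.0)) * 1e1 if pkill is not None else 0.0
        for diel in ("day", "night"):
            rows.append(
                {
                    "site_id": d["site_id"], "diel": diel,
                    "effort_days": float(days_per_site),
                    "V": V, "R": R, "E": E, "K": K,
                }
            )
    rows = pd.DataFrame(rows)
    truth_rows = simulate_counts(rows, truth, rng)

    photo_records = []
    for _, r in truth_rows.iterrows():
        ev_times = _event_times(rng, int(r["count"]), days_per_site, r["diel"], t0)
        for et in ev_times:
            n_photos = int(rng.integers(1, 4))
            offs = np.concatenate([[0.0], np.cumsum(rng.uniform(0.3, 4.5, n_photos - 1))])
            for o in offs:
                photo_records.append(
                    {
                        "site_id": r["site_id"], "species": species,
                        "timestamp": et + pd.Timedelta(minutes=float(o)),
                    }
                )
    photos = pd.DataFrame(photo_records, columns=["site_id", "species", "timestamp"])
    photos = photos.sort_values(["site_id", "timestamp"], kind="stable").reset_index(drop=True)
    return SurveyData(deployments=deployments, photos=photos, truth_rows=truth_rows)
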