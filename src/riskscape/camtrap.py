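"""Camera-trap records: independence filtering, diel classification, effort.

Raw photo tables are collapsed into independent detection events with a
rolling quiet-period rule (a photo starts a new event only when more than
the time-to-independence — 30 min by default — has elapsed since the
previous photo of the same species at the same site). Events are classified
as day or night from the solar elevation at the site, deployments shorter
than a minimum duration are excluded from analysis, and counts are
converted to group-abundance rates per 100 survey days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CameraDeployment",
    "DetectionEvent",
    "independent_events",
    "solar_elevation",
    "classify_diel",
    "effort_table",
    "group_abundance",
]

logger = logging.getLogger("riskscape")

DEFAULT_GAP_MIN = 30.0
DEFAULT_DEPRESSION_DEG = -0.833  # sunrise/sunset: refraction + solar radius
MIN_ACTIVE_DAYS = 30


@dataclass
class CameraDeployment:
    """A camera's placement and active window."""

    site_id: str
    x: float
    y: float
    start: pd.Timestamp
    end: pd.Timestamp
    lat: float | None = None
    lon: float | None = None

    @property
    def active_days(self) -> float:
        if self.end <= self.start:
            raise ValueError(f"site {self.site_id}: end must be after start")
        return (self.end - self.start) / pd.Timedelta(days=1)


@dataclass
class DetectionEvent:
    """An independent group observation of a species at a site."""

    site_id: str
    species: str
    event_time: pd.Timestamp
    diel: str | None = None  # "day" | "night"
    n_photos: int = 1


def independent_events(
    photos: pd.DataFrame, gap_min: float = DEFAULT_GAP_MIN
) -> pd.DataFrame:
    """Collapse photos into independent detection events per site and species.

    Rolling rule: within each (site_id, species) stream sorted by time, a
    photo opens a new event iff strictly more than ``gap_min`` minutes have
    elapsed since the *previous photo* (not the event start). A gap of
    exactly ``gap_min`` therefore keeps the photo in the running event.
    Events are groups, not individuals: multiple animals in one burst are a
    single record.

    Parameters
    ----------
    photos : DataFrame with columns site_id, species, timestamp
    gap_min : quiet period in minutes required to start a new event

    Returns
    -------
    DataFrame with columns site_id, species, event_time, n_photos,
    one row per independent event, ordered by site, species, time.
    """
    if gap_min < 0:
        raise ValueError("gap_min must be non-negative")
    required = {"site_id", "species", "timestamp"}
    if not required.issubset(photos.columns):
        raise ValueError(f"photos must have columns {sorted(required)}")
    if len(photos) == 0:
        return pd.DataFrame(columns=["site_id", "species", "event_time", "n_photos"])
    if photos["timestamp"].isna().any():
        raise ValueError("photos contain unparseable timestamps")

    df = photos.sort_values(["site_id", "species", "timestamp"], kind="stable")
    gap = pd.Timedelta(minutes=gap_min)
    grp = df.groupby(["site_id", "species"], sort=True, observed=True)
    new_event = grp["timestamp"].diff() > gap  # strict: == gap continues the event
    new_event |= grp.cumcount() == 0
    df = df.assign(_event=new_event.cumsum())
    ev = (
        df.groupby("_event", sort=True)
        .agg(
            site_id=("site_id", "first"),
            species=("species", "first"),
            event_time=("timestamp", "first"),
            n_photos=("timestamp", "size"),
        )
        .reset_index(drop=True)
    )
    return ev


# ---------------------------------------------------------------------------
# solar position (NOAA low-accuracy equations, good to ~0.1 deg elevation)
# ---------------------------------------------------------------------------

def solar_elevation(t_utc: pd.Timestamp | pd.Series, lat: float, lon: float):
    """Solar elevation angle (degrees) at UTC time(s) for a site.

    Uses the NOAA fractional-year series for the equation of time and solar
    declination. ``lon`` is degrees east, ``lat`` degrees north.
    """
    if not (-90 <= lat <= 90) or not (-180 <= lon <= 180):
        raise ValueError("invalid coordinates")
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(t_utc, dtype="datetime64[ns]")))
    doy = ts.dayofyear.to_numpy()
    frac_hour = (
        ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0 + ts.second.to_numpy() / 3600.0
    )
    gamma = 2 * np.pi / 365.0 * (doy - 1 + (frac_hour - 12) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    tst = frac_hour * 60.0 + eqtime + 4.0 * lon  # true solar time, minutes (UTC clock)
    ha = np.radians(tst / 4.0 - 180.0)
    lat_r = np.radians(lat)
    cos_zen = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    elev = 90.0 - np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    return elev if elev.size > 1 else float(elev[0])


def classify_diel(
    t,
    lat: float,
    lon: float,
    depression_deg: float = DEFAULT_DEPRESSION_DEG,
):
    """Classify timestamp(s) as "day" or "night" from local sun position.

    Day iff the solar elevation exceeds ``depression_deg`` (default
    -0.833 deg, the standard sunrise/sunset convention combining refraction
    and the solar radius; set -6 for civil twilight). Timestamps must be
    timezone-aware; they are converted to UTC internally. Latitudes beyond
    the polar circles are rejected (no polar day/night handling).
    """
    if abs(lat) >= 66.5:
        raise ValueError("polar latitudes are not supported")
    scalar = not isinstance(t, (pd.Series, pd.DatetimeIndex, np.ndarray, list))
    ts = pd.DatetimeIndex(pd.Series(t) if scalar else pd.Series(t))
    if ts.tz is None:
        raise ValueError("timestamps must be timezone-aware for diel classification")
    ts_utc = ts.tz_convert("UTC").tz_localize(None)
    elev = np.atleast_1d(solar_elevation(ts_utc, lat, lon))
    out = np.where(elev > depression_deg, "day", "night")
    return str(out[0]) if scalar else pd.Series(out, index=getattr(t, "index", None))


def effort_table(
    deployments: pd.DataFrame, min_days: float = MIN_ACTIVE_DAYS
) -> pd.DataFrame:
    """Per-site retained survey effort, stratified by diel period.

    Deployments active for fewer than ``min_days`` days are dropped (with a
    logged reason). Each retained site contributes two analysis strata, day
    and night, each carrying the full calendar-day effort (the model's time
    factor, not hour-level exposure, separates them).

    Returns a DataFrame with columns site_id, diel, effort_days.
    """
    required = {"site_id", "start", "end"}
    if not required.issubset(deployments.columns):
        raise ValueError(f"deployments must have columns {sorted(required)}")
    rows = []
    for _, d in deployments.iterrows():
        if d["end"] <= d["start"]:
            raise ValueError(f"site {d['site_id']}: end must be after start")
        days = (d["end"] - d["start"]) / pd.Timedelta(days=1)
        if days < min_days:
            logger.info(
                "site %s excluded: active %.1f days < %.0f-day minimum",
                d["site_id"], days, min_days,
            )
            continue
        for diel in ("day", "night"):
            rows.append({"site_id": d["site_id"], "diel": diel, "effort_days": days})
    return pd.DataFrame(rows, columns=["site_id", "diel", "effort_days"])


def group_abundance(n_events, effort_days):
    """Group abundance as observed groups per 100 survey days."""
    effort = np.asarray(effort_days, float)
    if np.any(effort <= 0):
        raise ValueError("effort_days must be positive")
    return np.asarray(n_events, float) * 100.0 / effort
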