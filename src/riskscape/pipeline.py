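"""End-to-end orchestration: config, validation, and the full analysis run.

A single declarative config drives the pipeline from inputs (synthetic or
files) to covariate tables, risk rasters, cluster/kill tables, per-species
model-selection tables, averaged coefficients, marginal curves, and a
provenance manifest. All of the analysis constants (500 m buffers, 30-min
independence, 100 m / 3-fix cluster rule, 0.6 h_ref, 10% isopleths,
rescale factors 10^3/10^1/10^1, 0.95 cumulative weight) are config
defaults, never hard-coded in the operations, and any override is logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import camtrap, glmm, predation, simulate, terrain
from .raster import Raster, read_ascii_grid, write_ascii_grid

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "shortterm_risk_table"]

logger = logging.getLogger("riskscape")

# lion kill-list species composition used by the synthetic kill labeller;
# medium-to-large herbivores plus a residual class of other species
DEFAULT_KILL_SPECIES_PROBS = {
    "ostrich": 0.37, "hartebeest": 0.20, "zebra": 0.07, "kudu": 0.09,
    "eland": 0.12, "buffalo": 0.01, "other": 0.14,
}


@dataclass
class PipelineConfig:
    """Declarative configuration for a full pipeline run."""

    # inputs: either a synthetic block or file paths
    synthetic: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    # analysis constants (defaults follow the study design)
    buffer_radius_m: float = 500.0
    gap_min: float = 30.0
    cluster_radius_m: float = 100.0
    min_fixes: int = 3
    href_multiplier: float = 0.6
    isopleth_step: int = 10
    rescale: dict = field(default_factory=lambda: {"R": 1e3, "E": 1e1, "K": 1e1})
    cum_weight: float = 0.95
    species: list = field(default_factory=lambda: ["herbivore"])
    risk_mode: str = "aggregated"  # or "restricted"
    min_active_days: float = 30.0
    subsample_k: int = 3
    ud_cell_m: float = 50.0
    depression_deg: float = -0.833
    lat: float = simulate.STUDY_LAT
    lon: float = simulate.STUDY_LON
    reference: str = "night"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.risk_mode not in ("aggregated", "restricted"):
            raise ValueError("risk_mode must be 'aggregated' or 'restricted'")
        if self.isopleth_step != 10:
            raise ValueError("only 10% isopleth steps are supported")
        defaults = PipelineConfig.__dataclass_fields__
        for name in ("buffer_radius_m", "gap_min", "cluster_radius_m", "min_fixes",
                     "href_multiplier", "cum_weight", "min_active_days", "subsample_k"):
            default = defaults[name].default
            if default is not dataclasses.MISSING and getattr(self, name) != default:
                logger.info("config override: %s = %r (default %r)", name, getattr(self, name), default)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: dict) -> dict:
    """Schema and sanity checks on input files.

    Returns a report {"errors": [...], "warnings": [...]}; an empty error
    list means the inputs are usable. Checks per-animal timestamp
    monotonicity (with offending row numbers), camera coordinates against
    the raster extent, and non-negative counts where present.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    dem = None
    if "dem" in paths:
        try:
            dem = read_ascii_grid(paths["dem"])
        except Exception as exc:  # unreadable file is an error
            errors.append(f"dem: unreadable ({exc})")
    if "fixes" in paths:
        try:
            fx = pd.read_csv(paths["fixes"], parse_dates=["timestamp"])
            for animal, grp in fx.groupby("animal_id"):
                bad = grp.index[grp["timestamp"].diff() < pd.Timedelta(0)]
                if len(bad):
                    errors.append(
                        f"fixes: animal {animal} has decreasing timestamps at rows {list(bad)}"
                    )
            if dem is not None:
                outside = ~dem.contains(fx["x"].to_numpy(), fx["y"].to_numpy())
                if outside.any():
                    warnings_.append(f"fixes: {int(outside.sum())} fixes outside raster extent")
        except Exception as exc:
            errors.append(f"fixes: {exc}")
    if "deployments" in paths:
        try:
            dep = pd.read_csv(paths["deployments"], parse_dates=["start", "end"])
            if (dep["end"] <= dep["start"]).any():
                errors.append("deployments: end <= start for some sites")
            if dem is not None:
                outside = ~dem.contains(dep["x"].to_numpy(), dep["y"].to_numpy())
                for sid in dep.loc[outside, "site_id"]:
                    warnings_.append(
                        f"deployments: site {sid} outside raster extent (buffer may be truncated)"
                    )
        except Exception as exc:
            errors.append(f"deployments: {exc}")
    if "photos" in paths:
        try:
            ph = pd.read_csv(paths["photos"], parse_dates=["timestamp"])
            if ph["timestamp"].isna().any():
                errors.append("photos: unparseable timestamps")
        except Exception as exc:
            errors.append(f"photos: {exc}")
    if "rows" in paths:
        try:
            rows = pd.read_csv(paths["rows"])
            if (rows["count"] < 0).any():
                errors.append("rows: negative counts")
        except Exception as exc:
            errors.append(f"rows: {exc}")
    return {"errors": errors, "warnings": warnings_}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _synthetic_inputs(config: PipelineConfig):
    """Generate landscape, tracks, risk surface, kills and survey data."""
    syn = dict(config.synthetic)
    rng = np.random.default_rng(config.seed)
    land = simulate.LandscapeConfig(
        extent_m=syn.get("extent_m", 2000.0),
        cell_m=syn.get("cell_m", 10.0),
        veg_gradient=syn.get("veg_gradient", 0.5),
        ruggedness_scale=syn.get("ruggedness_scale", 15.0),
        seed=config.seed,
    )
    dem, chm = simulate.gen_landscape(land)
    xmin, ymin, xmax, ymax = dem.extent
    n_clusters = syn.get("n_clusters", 8)
    cluster_spec = [
        (
            (rng.uniform(xmin + 150, xmax - 150), rng.uniform(ymin + 150, ymax - 150)),
            int(rng.integers(3, 7)),
        )
        for _ in range(n_clusters)
    ]
    tracks = simulate.gen_lion_tracks(
        dem,
        n_lions=syn.get("n_lions", 2),
        fixes_per_day=syn.get("fixes_per_day", 5),
        n_days=syn.get("n_days", 60),
        cluster_spec=cluster_spec,
        seed=config.seed + 1,
        start=syn.get("track_start", "2013-01-01 00:00:00"),
    )
    return dem, chm, tracks


def _risk_stage(config: PipelineConfig, dem: Raster, tracks: list[predation.GpsTrack]):
    """Subsample tracks, build the combined encounter-risk raster and kills."""
    sub = [predation.subsample_daily(t, config.subsample_k) for t in tracks]
    n = max(3, int(round((dem.extent[2] - dem.extent[0]) / config.ud_cell_m)))
    grid = Raster(np.zeros((n, n)), config.ud_cell_m, dem.origin)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # coverage warning expected near study edge
        risk, uds = predation.combined_encounter_risk(
            sub, grid, href_multiplier=config.href_multiplier
        )
    clusters = []
    for t in tracks:
        clusters.extend(
            predation.detect_clusters(t, config.cluster_radius_m, config.min_fixes)
        )
    rng = np.random.default_rng(config.seed + 2)
    probs = DEFAULT_KILL_SPECIES_PROBS
    names = list(probs)
    p = np.array([probs[s] for s in names])
    p = p / p.sum()
    kills = pd.DataFrame(
        {
            "x": [c.centroid[0] for c in clusters],
            "y": [c.centroid[1] for c in clusters],
            "species": rng.choice(names, size=len(clusters), p=p),
            "source": rng.choice(["stomach", "carcass"], size=len(clusters), p=[125 / 206, 81 / 206]),
        }
    )
    for c, sp, src in zip(clusters, kills.get("species", []), kills.get("source", [])):
        c.kill = (sp, src)
    return sub, risk, uds, clusters, kills


def shortterm_risk_table(
    subsampled: list[predation.GpsTrack],
    deployments: pd.DataFrame,
    radius_m: float = 500.0,
) -> pd.Series:
    """Short-term encounter risk per site, pooling all collared animals.

    Numerators (fixes in buffer) and denominators (fixes anywhere) are
    summed over animals within each camera's active window; sites with no
    overlapping fixes get NaN and are excluded from restricted-risk models.
    """
    out = {}
    for _, d in deployments.iterrows():
        num = den = 0
        for tr in subsampled:
            fx = tr.fixes
            in_win = (fx["timestamp"] >= d["start"]) & (fx["timestamp"] <= d["end"])
            den += int(in_win.sum())
            sel = fx.loc[in_win]
            d2 = (sel["x"] - d["x"]) ** 2 + (sel["y"] - d["y"]) ** 2
            num += int((d2 <= radius_m**2).sum())
        out[d["site_id"]] = num / den if den > 0 else np.nan
    return pd.Series(out, name="enc_short")


def _clusters_frame(clusters: list[predation.Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": range(len(clusters)),
            "animal_id": [c.animal_id for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "x": [c.centroid[0] for c in clusters],
            "y": [c.centroid[1] for c in clusters],
            "n_fixes": [c.n_fixes for c in clusters],
            "kill_species": [c.kill[0] if c.kill else "" for c in clusters],
        }
    )


def build_observation_rows(
    events: pd.DataFrame,
    effort: pd.DataFrame,
    covariates: pd.DataFrame,
    species: str,
) -> pd.DataFrame:
    """Join event counts per site/diel stratum with effort and covariates."""
    ev = events[events["species"] == species]
    counts = (
        ev.groupby(["site_id", "diel"], observed=True).size().rename("count").reset_index()
    )
    rows = effort.merge(counts, on=["site_id", "diel"], how="left")
    rows["count"] = rows["count"].fillna(0).astype(int)
    rows = rows.merge(covariates, on="site_id", how="inner")
    return rows


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the whole analysis and write the output bundle.

    Deterministic given config + seed. Returns a dict of the in-memory
    results (rasters, tables, fits) in addition to writing CSV/raster/JSON
    outputs under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    if config.synthetic or not config.paths:
        dem, chm, tracks = _synthetic_inputs(config)
        deployments = photos = None
    else:
        report = validate_inputs(config.paths)
        if report["errors"]:
            raise ValueError("input validation failed: " + "; ".join(report["errors"]))
        dem = read_ascii_grid(config.paths["dem"])
        chm = read_ascii_grid(config.paths["chm"]) if "chm" in config.paths else None
        fx = pd.read_csv(config.paths["fixes"], parse_dates=["timestamp"])
        tracks = [
            predation.GpsTrack(str(a), g.reset_index(drop=True)[["timestamp", "x", "y"]])
            for a, g in fx.groupby("animal_id")
        ]
        deployments = pd.read_csv(config.paths["deployments"], parse_dates=["start", "end"])
        photos = pd.read_csv(config.paths["photos"], parse_dates=["timestamp"])

    # ---- terrain covariate stack -----------------------------------------
    dem10 = terrain.resample_bilinear(dem, 10.0) if dem.cell_m < 10.0 else dem
    slope_r, _aspect_r = terrain.slope_aspect(dem10)
    vrm_r = terrain.vrm(dem10, window=3)
    veg_r = terrain.vegetation_density(chm) if chm is not None else None

    # ---- predation risk ---------------------------------------------------
    sub, risk_r, uds, clusters, kills = _risk_stage(config, dem, tracks)

    # ---- camera survey (synthetic mode simulates it on this landscape) ----
    if deployments is None:
        syn = dict(config.synthetic)
        truth = simulate.TruthModel(
            beta=syn.get("beta", {"T": -0.9, "V": -2.0, "T:V": 0.4}),
            sigma_camera=syn.get("sigma_camera", 0.5),
            baseline_rate=syn.get("baseline_rate", 20.0),
        )
        survey = simulate.gen_camera_survey(
            dem10, chm, risk_r, truth,
            n_sites=syn.get("n_sites", 24),
            days_per_site=syn.get("days_per_site", 100),
            seed=config.seed + 3,
            species=config.species[0],
            buffer_radius_m=config.buffer_radius_m,
        )
        deployments, photos = survey.deployments, survey.photos

    effort = camtrap.effort_table(deployments, config.min_active_days)
    events = camtrap.independent_events(photos, config.gap_min)
    events["diel"] = camtrap.classify_diel(
        events["event_time"], config.lat, config.lon, config.depression_deg
    ).to_numpy()

    # ---- per-site covariates ---------------------------------------------
    pkill = predation.kill_probability(
        kills[["x", "y"]].to_numpy(), deployments, config.buffer_radius_m
    ) if len(kills) else pd.Series(dtype=float)
    enc_short = shortterm_risk_table(sub, deployments, config.buffer_radius_m)
    cov_rows = []
    for _, d in deployments.iterrows():
        center = (d["x"], d["y"])
        cov_rows.append(
            {
                "site_id": d["site_id"],
                "veg": terrain.buffer_mean(veg_r, center, config.buffer_radius_m) if veg_r is not None else 0.0,
                "vrm": terrain.buffer_mean(vrm_r, center, config.buffer_radius_m),
                "slope": terrain.buffer_mean(slope_r, center, config.buffer_radius_m),
                "enc_long": terrain.buffer_mean(risk_r, center, config.buffer_radius_m),
                "enc_short": enc_short.get(d["site_id"], np.nan),
                "pkill": float(pkill.get(d["site_id"], 0.0)),
            }
        )
    covariates = pd.DataFrame(cov_rows)

    enc_col = "enc_long" if config.risk_mode == "aggregated" else "enc_short"
    model_cov = pd.DataFrame(
        {
            "site_id": covariates["site_id"],
            "V": covariates["veg"],
            "R": covariates["vrm"] * config.rescale["R"],
            "E": covariates[enc_col] * config.rescale["E"],
            "K": covariates["pkill"] * config.rescale["K"],
        }
    ).dropna(subset=["E"])

    # ---- models -----------------------------------------------------------
    results: dict = {
        "dem": dem10, "veg": veg_r, "vrm": vrm_r, "slope": slope_r, "risk": risk_r,
        "uds": uds, "clusters": clusters, "kills": kills, "events": events,
        "effort": effort, "covariates": covariates, "fits": {}, "tables": {},
        "averaged": {}, "curves": {}, "vif": None,
    }
    try:
        vif, rho = glmm.vif_screen(model_cov, ["V", "R", "E", "K"])
        results["vif"] = vif
    except ValueError:
        rho = None

    for sp in config.species:
        rows = build_observation_rows(events, effort, model_cov, sp)
        if rows["count"].sum() == 0 or rows["site_id"].nunique() < 2:
            logger.warning("species %s: too little data, skipped", sp)
            continue
        fits = [glmm.fit_poisson_glmm(rows, s, reference=config.reference) for s in glmm.candidate_set()]
        table = glmm.model_selection_table(fits)
        avg = glmm.model_average(fits, config.cum_weight)
        best = min((f for f in fits if f.converged), key=lambda f: f.aicc)
        curves = {}
        for term in best.spec.terms:
            if ":" in term or term == "T":
                continue
            curves[term] = glmm.marginal_curve(best, rows, term)
        results["fits"][sp] = fits
        results["tables"][sp] = table
        results["averaged"][sp] = avg
        results["curves"][sp] = curves
        results[f"rows_{sp}"] = rows

        table.to_csv(outdir / f"model_table_{sp}.csv", index=False)
        best.coef_table.to_csv(outdir / f"coefficients_{sp}.csv")
        pd.DataFrame({"beta": avg.beta, "se": avg.se}).to_csv(outdir / f"averaged_{sp}.csv")
        rows.to_csv(outdir / f"rows_{sp}.csv", index=False)
        for term, curve in curves.items():
            curve.to_csv(outdir / f"curve_{sp}_{term}.csv", index=False)

    # ---- outputs ----------------------------------------------------------
    for name, r in (("vrm10", vrm_r), ("slope10", slope_r), ("risk", risk_r)):
        write_ascii_grid(r, outdir / f"{name}.asc")
    if veg_r is not None:
        write_ascii_grid(veg_r, outdir / "vegdensity.asc")
    pd.concat(
        [t.fixes.assign(animal_id=t.animal_id) for t in tracks], ignore_index=True
    )[["animal_id", "timestamp", "x", "y"]].to_csv(outdir / "fixes.csv", index=False)
    deployments.to_csv(outdir / "deployments.csv", index=False)
    photos.to_csv(outdir / "photos.csv", index=False)
    events.to_csv(outdir / "events.csv", index=False)
    effort.to_csv(outdir / "effort.csv", index=False)
    _clusters_frame(clusters).to_csv(outdir / "clusters.csv", index=False)
    kills.to_csv(outdir / "kills.csv", index=False)
    covariates.to_csv(outdir / "covariates.csv", index=False)

    import riskscape

    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {
            "riskscape": riskscape.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
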