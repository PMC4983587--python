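"""Shared fixtures: a synthetic landscape, risk surface and survey base.

Session-scoped because landscape and kernel-UD construction dominate test
runtime; all downstream tests treat these as read-only.
"""

import warnings

import numpy as np
import pytest

import riskscape as rs


@pytest.fixture(scope="session", autouse=True)
def _quiet_warnings():
    warnings.filterwarnings("ignore", message="UD grid does not cover")


@pytest.fixture(scope="session")
def landscape():
    cfg = rs.LandscapeConfig(extent_m=2000.0, cell_m=10.0, veg_gradient=0.5,
                             ruggedness_scale=15.0, seed=7)
    dem, chm = rs.gen_landscape(cfg)
    return cfg, dem, chm


@pytest.fixture(scope="session")
def risk_raster(landscape):
    _, dem, _ = landscape
    tracks = rs.gen_lion_tracks(dem, n_lions=2, fixes_per_day=5, n_days=120,
                                seed=9, step_sd=200.0)
    sub = [rs.subsample_daily(t) for t in tracks]
    grid = rs.Raster(np.zeros((40, 40)), 50.0, (0.0, 0.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        risk, uds = rs.combined_encounter_risk(sub, grid)
    return risk, uds, tracks


@pytest.fixture(scope="session")
def survey_base(landscape, risk_raster):
    """Observation rows (63 sites x 2 diel strata) with varying V, R, E, K."""
    _, dem, chm = landscape
    risk, _, _ = risk_raster
    truth = rs.TruthModel(beta={"T": -0.9, "V": -2.5, "T:V": 0.8},
                          sigma_camera=0.5, baseline_rate=20.0)
    sv = rs.gen_camera_survey(dem, chm, risk, truth, n_sites=63,
                              days_per_site=100, seed=2)
    base = sv.truth_rows[["site_id", "diel", "effort_days", "V", "R", "E", "K"]].copy()
    # kill probability varies by site in the real pipeline; here it is an
    # independent site attribute so models using K are identifiable
    rng = np.random.default_rng(42)
    sites = base["site_id"].unique()
    kmap = dict(zip(sites, rng.uniform(0.0, 0.3, len(sites)) * 10.0))
    base["K"] = base["site_id"].map(kmap)
    return base, truth, sv
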