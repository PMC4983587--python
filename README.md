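# riskscape

Spatial predation-risk analysis for camera-trap prey surveys: from predator
GPS telemetry, kill-site investigations, camera-trap photo records and
LiDAR-derived terrain rasters to per-site risk covariates and Poisson
mixed models of herbivore group abundance.

The package targets the common study design in large-mammal movement
ecology where a small, collared predator population (here, reintroduced
lions in a fenced subtropical thicket reserve) shares a landscape with a
camera-trap grid sampling the prey community. It answers: do prey
distributions track habitat (vegetation density, terrain ruggedness) or
direct predation risk (predator encounter risk, kill probability), and do
those responses differ between day and night?

## The analysis

**Covariates** per camera site, as means within a 500 m buffer:

- *Vegetation density* `V`: fraction of 1 m canopy-height cells above 1 m,
  aggregated to 10 m cells from a canopy height model.
- *Terrain ruggedness* `R`: vector ruggedness measure (VRM) in a 3×3
  window on the 10 m bilinear-resampled DEM,
  `VRM = 1 − |Σ unit surface normals| / n`.
- *Long-term encounter risk* `E`: from each collared predator's kernel
  utilization distribution (bandwidth `0.6 h_ref`,
  `h_ref = sqrt((s²_x + s²_y)/2) · n^(−1/6)`), consecutive 10% isopleths
  with areas `A₁₀ < … < A₁₀₀` give a presence probability per km² of
  `0.1 / (Aᵢ − Aᵢ₋₁₀)` inside each annulus (10% of fixes lie between
  consecutive isopleths). Per-animal surfaces are averaged weighted by fix
  share. A *short-term* variant restricts fixes to each camera's active
  window.
- *Kill probability* `K`: the proportion of investigated kills (GPS
  clusters — runs of >2 consecutive fixes staying within 100 m of their
  running centroid — verified as feeding sites) inside the site's buffer.

**Response**: independent detection events (photos of a species at a site
collapsed with a 30-min time-to-independence rule), classified day/night by
solar elevation, per site × diel stratum; deployments under 30 days are
excluded. Counts are modelled as

    count ~ Poisson(exp(log(effort/100) + Xβ + b_site)),  b_site ~ N(0, σ²)

fitted by maximum marginal likelihood (Laplace approximation; adaptive
Gauss–Hermite as a verification mode), so coefficients are log group
abundance per 100 survey days. A 14-model candidate set over
`{T, V, R, E, K}` and their admissible two-way interactions is ranked by
AICc; when no model holds ≥0.95 Akaike weight, coefficients are averaged
over the 0.95 cumulative-weight set with Burnham–Anderson unconditional
SEs. Marginal response curves profile each predictor at 40 values,
reporting the median of `1 − exp(−μ)` (probability of ≥1 group) across
observation rows.

A seeded synthetic-data module (`riskscape.simulate`) generates every
input — landscape rasters, clumped predator tracks with planted feeding
clusters, camera deployments and photo streams — with known ground truth,
so the whole pipeline is testable without field data.

## Worked example

Simulate a survey whose counts are generated from a known model
(`T + V + T:V` with β = (−0.9, −2.5, 0.8), site SD 0.5, 20 groups/100
days at baseline), then refit the whole candidate set:

```python
import numpy as np
import riskscape as rs

dem, chm = rs.gen_landscape(rs.LandscapeConfig(extent_m=2000, seed=7))
tracks = rs.gen_lion_tracks(dem, n_lions=2, fixes_per_day=5, n_days=120,
                            seed=9, step_sd=200.0)
sub = [rs.subsample_daily(t) for t in tracks]
risk, _ = rs.combined_encounter_risk(sub, rs.Raster(np.zeros((40, 40)), 50.0))
kills = np.array([c.centroid for t in tracks for c in rs.detect_clusters(t)])

truth = rs.TruthModel(beta={"T": -0.9, "V": -2.5, "T:V": 0.8},
                      sigma_camera=0.5, baseline_rate=20.0)
sv = rs.gen_camera_survey(dem, chm, risk, truth, n_sites=63,
                          days_per_site=100, seed=4)
rows = sv.truth_rows.copy()
rows["K"] = rows["site_id"].map(
    rs.kill_probability(kills, sv.deployments, 500.0)) * 10.0

fits = [rs.fit_poisson_glmm(rows, s) for s in rs.candidate_set()]
print(rs.model_selection_table(fits).head(3).round(2).to_string(index=False))
```

```
            model  k  logLik   AICc  dAICc  weight
          T+V+T:V  5 -297.61 605.71   0.00    0.63
    T+V+R+T:V+T:R  7 -297.03 609.00   3.29    0.12
T+R+E+T:R+T:E+R:E  8 -296.56 610.35   4.64    0.06
```

The generating structure ranks first with Akaike weight 0.63, and its
coefficient table recovers the simulated values within sampling error
(β̂ = −0.85, −2.59, 0.63; `sigma_site` = 0.45). Because the best model
carries <0.95 of the weight, `rs.model_average(fits)` averages the
coefficients over the 0.95 cumulative-weight confidence set (seven models
here), attaching unconditional standard errors.

Or end-to-end from a config:

```bash
riskscape all --seed 3 --out run/
```

writes covariate and event tables, risk rasters, the per-species model
table, averaged coefficients, marginal curves and a provenance manifest.

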