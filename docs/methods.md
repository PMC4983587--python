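# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `riskscape`, in the order the pipeline runs.

## Rasters and terrain covariates

Rasters are square-celled grids in a projected planar CRS (meters), stored
as ESRI ASCII grids. The study systems this pipeline targets are a few
hundred km² at most, so no geodesy is used; distances are Euclidean.

- **Bilinear resampling** interpolates cell-center values onto the coarser
  target grid (the ground DEM to 10 m before any derivative). Nodata
  neighbours are dropped with weight renormalisation; an all-nodata
  neighbourhood yields nodata.
- **Slope/aspect** use Horn's 3×3 finite differences — the de-facto GIS
  standard and the method underlying the reference VRM implementation.
  Aspect is reported as the *uphill* direction clockwise from north and is
  flagged undefined where the gradient vanishes. The VRM is insensitive to
  the uphill/downhill convention (flipping every horizontal normal
  component coherently leaves the resultant length unchanged).
- **VRM** (vector ruggedness measure): each cell's unit surface normal
  (from slope θ and aspect α: `(sinθ sinα, sinθ cosα, cosθ)`) is summed
  over a w×w window (default 3×3) and `VRM = 1 − |Σ| / w²` ∈ [0, 1]; 0 for
  flat *or uniformly inclined* terrain. Edges use edge-replication
  padding; the outermost ring therefore underestimates the gradient and is
  best discarded for inference on small rasters (buffer means at 500 m on
  landscape-scale rasters are unaffected in practice).
- **Vegetation density**: the fraction of 1 m canopy-height cells above a
  1 m height threshold within each 10 m analysis cell (vegetation below
  1 m is treated as irrelevant to predation risk). The fine grid must tile
  the coarse grid exactly; misalignment is an error, not a resample.
- **Buffer means** use the cell-center-in-circle rule (no partial-cell
  weighting): at 10 m cells against a 500 m radius the discretisation
  error is negligible and unbiased. "Interpolated mean" is interpreted as
  the mean of the bilinear-resampled 10 m surface within the buffer.

## Encounter risk from kernel UDs

The long-term encounter-risk index treats each collared predator's kernel
utilization distribution as a map of presence probability:

1. Bandwidth `h = 0.6 · h_ref`, `h_ref = sqrt((s²x + s²y)/2) · n^(−1/6)`
   (bivariate normal reference bandwidth, sample variances). The 0.6
   shrinkage counteracts the over-smoothing of h_ref on clumped fixes.
2. A single scalar bandwidth and a Gaussian kernel are used (h_ref theory
   assumes both); the density is evaluated exactly at cell centers (no
   binned FFT approximation) and normalised to unit mass over the grid.
3. Isopleth areas A₁₀ … A₁₀₀ come from sorting cell masses in descending
   order and accumulating — the raster equivalent of "smallest region
   containing i% of the UD". No contour polygons are built: only the
   areas enter the risk formula.
4. Every cell between isopleths i−10 and i receives
   `0.1 / (Aᵢ − Aᵢ₋₁₀)` km⁻²; the innermost region gets `0.1/A₁₀`.
   Because each annulus holds exactly 10% of the mass, the surface
   integrates to 1 by construction. A zero-area annulus (possible on
   coarse grids) is merged with the annulus inside it, with a logged
   warning.
5. Multiple collared animals: per-animal risk surfaces are averaged,
   weighted by each animal's share of total fixes (override available).
   This is the neutral choice when one collared male represents a
   coalition whose members move together; the weights are config.

The UD grid resolution is a config default (50 m); at the 500 m buffer
scale the extracted means are insensitive to it.

Fixes are first thinned to 3 per day (nearest to 06:00/14:00/22:00,
evenly spaced for other k) so collars with different duty cycles
contribute equally. Short-term risk divides, per camera window, the
subsampled fixes inside the buffer by all subsampled fixes in the window,
pooled over animals; windows with no fixes give a missing value and the
site drops out of restricted-risk models.

## Kill sites

Potential kill sites are runs of consecutive fixes staying strictly within
100 m of their *running centroid* for more than two locations (min 3
fixes). The scan is greedy and sequential: a candidate opens at each fix,
extends while the next fix is `< 100 m` from the updated centroid, and
emitted runs do not overlap. The kill location is the cluster centroid
(the stomach-contents/carcass distinction is metadata; at a 500 m buffer
scale the exact position is immaterial). Kill probability per site is the
proportion of all supplied kills inside the buffer; callers choose the
denominator subset (e.g. medium-to-large herbivores only), and a kill may
count toward several overlapping buffers.

## Camera-trap events

Photos collapse into independent events per site × species with a rolling
quiet-period rule: a photo starts a new event only when strictly more than
30 min (config) elapsed since the previous photo of that species at that
site. A gap of exactly 30 min therefore keeps the chain open — "time to
independence" is read as the minimum separation that must be *exceeded*.
Events are groups, not individual counts.

Day/night classification uses the NOAA low-accuracy solar-position series
with a −0.833° depression angle (sunset/sunrise convention: refraction +
solar radius); civil twilight (−6°) is a config alternative. Polar
latitudes are rejected. Deployments under 30 days are excluded; retained
sites contribute a day and a night stratum, each carrying the full
calendar-day effort — the model's time-of-day factor, not hour-level
exposure, separates the strata (a documented simplification).

## The abundance model

Per observation row (site × diel stratum):

    count ~ Poisson(exp(log(effort_days/100) + Xβ + b_site)),
    b_site ~ Normal(0, σ²)

The response is the integer event count with a log-effort offset — never
the precomputed rate, which has no Poisson likelihood — so coefficients
are on the log scale of groups per 100 days. The time factor T defaults to
reference level *night* (T = 1 by day); the reference is config.
Covariates enter as 500 m buffer means, rescaled once (VRM ×10³,
encounter risk ×10¹, kill probability ×10¹) to put predictors on similar
scales.

**Estimation.** The marginal likelihood integrates b out per site. The
default is a Laplace approximation: the per-site mode b̂ solves the scalar
concave equation `Σy − e^b Σe^η − b/σ² = 0` (vectorised Newton across
sites, tolerance 1e-12), giving
`ℓᵢ = joint(b̂) − ½ log(1 + σ² e^{b̂} Σe^η)`. Adaptive Gauss–Hermite
quadrature (≥9 nodes, default 9, verification runs use 25) centers and
scales the nodes at the Laplace mode; it matches brute-force numerical
integration to machine precision and bounds the Laplace error (which
shrinks as per-site information grows — below 1e-3 once site totals reach
a few hundred counts). The outer optimisation is L-BFGS-B over (β, log σ)
with a Nelder–Mead polish if a line search stalls; Wald SEs come from the
numerically differentiated observed information. When σ̂ falls below 1e-3
the fit is profiled to the exact σ = 0 limit, a plain Poisson GLM
(statsmodels), and flagged `sigma_site = 0`. Non-converged fits are
excluded from model selection with a logged warning rather than silently
contaminating the weights.

**Selection and averaging.** AICc uses n = number of observation rows and
k = fixed effects + intercept + σ. Models whose k exceeds what n supports
(n ≤ k+1) are excluded with a warning — relevant only for very small
surveys. The 14-model candidate set spans the null, time-only, habitat
(V, R), direct-risk (E, K) and combined structures; every covariate is
accompanied by its time interaction and the mixed models add habitat ×
risk interactions; the set is an ordinary list and fully overridable (the
published analysis names fourteen models but does not print the full set;
this one follows its stated interaction families and the structures
visible in its best models). If the best model holds ≥0.95 Akaike weight
it is reported alone; otherwise coefficients are averaged over the
smallest cumulative-0.95 set, *conditionally* (natural averaging: each
term over the models containing it, weights renormalised), with
Burnham–Anderson unconditional SEs
`Σ wᵢ sqrt(seᵢ² + (βᵢ − β̄)²)`. Full-shrinkage averaging is deliberately
not the default.

**Screening and curves.** VIFs are `1/(1 − R²)` from OLS of each predictor
on the rest (∞ reported for exact collinearity, never raised), with a
Spearman matrix; the caller decides what to drop (slope is the usual
casualty, being collinear with VRM and vegetation density). Marginal
curves fix the focal predictor at 40 evenly spaced values over its
observed range, keep every row's other covariates, offset and estimated
random intercept, and summarise presence probability `1 − exp(−μ)` by the
median and quartiles across rows.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical* structure the analysis assumes,
at a reduced spatial scale (a 2 km × 2 km landscape rather than 140 km²;
all operators are resolution- and extent-agnostic, so this only shortens
runtimes):

- **Landscape**: elevation is unit-variance Gaussian-filtered white noise
  at two length scales (no terrain model is prescribed by the study
  design; this gives continuous slope/VRM fields with one amplitude knob,
  `ruggedness_scale`, in meters), ramped so the north is rugged and the
  south flat. The canopy height model marks a dense-thicket region (crowns
  3–5 m) against open plains (scattered cover < 1.2 m), split so a
  `veg_gradient` fraction of the area is open, biased open toward the
  south.
- **Tracks**: a biased random walk pulled toward 1–3 activity centers
  (clumped UDs, so 10% isopleths are informative), 3–5 fixes/day.
  Requested feeding clusters overwrite consecutive fixes within ~30 m of
  a center. An optional minimum step length makes the background walk
  provably cluster-free for detection tests. Boundaries reject-and-resample
  rather than clip (clipping would fabricate stationary runs at fences).
- **Survey**: sites on a regular grid; covariates extracted from the same
  rasters the analysis later uses, so parameter recovery is exact up to
  sampling noise. Counts per site × stratum are Poisson with the model's
  own log-linear form and a Normal(0, σ²) camera intercept
  (defaults: σ = 0.5, 20 groups/100 days at baseline, 63 sites, 100-day
  deployments — the surveyed design's scale). Events are placed in
  diel-safe clock windows (09:00–15:00 day, 20:00–early-night) in 45-min
  slots, with 1–3 photos ≤5 min apart per event, so the 30-min filter
  recovers the generating counts *exactly* and day/night classification
  is unambiguous.

Not emulated: hunting-mode mechanics, prey depletion, collar fix failure,
camera detection distance/imperfect detection, multi-predator guilds, or
spatial autocorrelation beyond what the shared rasters induce. Passing
tests therefore certify the estimators and the pipeline plumbing, not the
ecological realism of any particular field system.

## Degenerate inputs and tie-breaks

- All-identical points: `href` raises (zero bandwidth is meaningless).
- A UD grid not covering the fixes ±3h: warning, mass renormalised.
- Duplicate photo timestamps (burst pairs) are legal and merge into one
  event; negative filter gaps are input errors.
- Days with fewer than k fixes keep all fixes during subsampling; when two
  targets select the same fix the later target takes the next-nearest
  unused fix.
- Empty kill lists and zero-effort strata are errors, not zeros.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` uses: 1000-fix tracks for UD calibration; 100
tracks × 5 planted clusters for detection; 200 replicate surveys at
63 sites × 100 days for CI coverage and bias; 100 replicates × 14 models
for selection frequencies; 365 days for the sunrise comparison. These
match the sizes the test suite asserts against.
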