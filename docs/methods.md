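# Methods

This note documents the statistical procedures implemented in
`laggedsdm`, the synthetic study system used to exercise them, and the
numerical and design choices a user should know before trusting (or
changing) the defaults.

## 1. Analysis chain

### 1.1 Conventional distance sampling

Perpendicular distances are analysed as exact values (not binned),
right-truncated at `w = 0.4` km. Two detection keys are supported —
half-normal `g(x) = exp(−x²/2σ²)` and hazard-rate
`g(x) = 1 − exp(−(x/σ)^−b)` with shape `b > 1` — fitted by maximizing
the truncated-density likelihood `Σ log g(xᵢ) − n log ∫₀ʷ g`. The
optimizer is deterministic: bounded scalar search on `log σ` for the
half-normal (start `σ₀` = sd of distances), Nelder–Mead on
`(log σ, log(b−1))` for the hazard-rate. Standard errors come from the
numerical Hessian on the transformed scale; the CI on `σ` is lognormal
(`σ̂·exp(±1.96·se)`), and the ESW interval follows by the delta method.
No covariates enter the detection function (conventional, not
multi-covariate, distance sampling), so condition filtering is the only
guard against detectability heterogeneity.

Density per stratum is `D̂ = Σsᵢ / (2·ESW·ΣLᵢ)` with squared CV equal to
the sum of the encounter-rate and ESW squared CVs. The encounter-rate
variance uses the length-weighted among-segment estimator
`k/(L²(k−1)) Σ lᵢ²(nᵢ/lᵢ − n/L)²`. Per-day estimates reuse the
survey-level ESW rather than refitting per day — daily sighting counts
are far too small to identify σ daily.

### 1.2 Penalized Tweedie count regression

The shared engine behind lag screening, model selection and prediction
is a count GAM: response = individuals per segment, family =
Tweedie(p) with `1 < p < 2` and log link, offset = `log(2·ESW·L)`
(the effectively sampled area in km², so predictions with offset 0 are
densities per km²).

* **Basis.** Each smooth is a cubic B-spline basis of dimension 4 on
  the covariate's observed range (scaled to [0, 1]), with a sum-to-zero
  constraint absorbed by a null-space reparameterization (3 free
  coefficients per term plus the global intercept). Beyond-range
  predictions clamp to the boundary value — consistent with quantile
  saturation upstream and flagged separately by the extrapolation
  diagnostic.
* **Penalty and smoothing.** Squared second differences of the basis
  coefficients, normalized to unit trace per term; a single smoothing
  parameter shared across terms is selected by GCV
  `n·D/(n − 1.4·edf)²` over a fixed grid `10⁻⁴…10⁶` (21 points,
  deterministic). The 1.4 inflation is the standard guard against
  occasional severe GCV undersmoothing; without it, pure-noise
  covariates are over-retained in the lag screen.
* **Likelihood and AIC.** The Tweedie log-density is evaluated exactly:
  point mass `exp(−μ^{2−p}/(φ(2−p)))` at zero and the Dunn–Smyth series
  for positive values (verified against an independent R implementation
  to 5·10⁻¹¹). Dispersion φ is the Pearson estimate with `n − edf`
  denominator; `AIC = −2ℓ + 2(edf + 1)`, where edf is the trace of the
  penalized influence matrix and the +1 accounts for φ. The power p is
  profiled over `1.1, …, 1.9` when not fixed; batch comparisons (the
  eight lag models of one variable, the combination stage) profile p
  once and then hold it fixed so AICs are comparable within the set.
* **Convergence.** IRLS to a relative deviance change below 10⁻⁸, at
  most 200 iterations; non-convergence and rank-deficient designs raise
  (with the offending terms named); in the combination stage individual
  failures are logged and excluded rather than fatal.
* **Uncertainty.** Coefficient covariance is the Bayesian form
  `φ(XᵀWX + S)⁻¹` (penalty as prior); prediction SEs are delta-method
  on the response scale. No posterior simulation.

### 1.3 Lag screening and variable pre-selection

For each dynamic variable: eight models (lags 0, 1, 2, 4, 7, 10, 30
plus the intercept-only null), ranked by AIC; ΔAIC, relative likelihood
and Akaike weights computed over the eight. Retained lags are those
with ΔAIC < 2. A variable is discarded when its best lag's weight is
below 50% or when the null model itself is within ΔAIC < 2 of the best
lag ("did not perform better than the null" is operationalized as this
ΔAIC rule; a pairwise-weight variant is a one-line change). Static,
season-scale variables are screened against the null only and retained
when they beat it by at least 2 AIC. Exact AIC ties resolve to the
shortest lag (stable sort over increasing lags).

### 1.4 Exhaustive combination stage

All subsets of 1–4 candidates are fitted, excluding any subset with a
pair correlated beyond |r| > 0.6 (Pearson on the saturated covariates
over analysis segments; Spearman by flag). Two lags of one variable
are treated as correlation 1 by construction, so they never co-occur —
and a threshold of exactly 1.0 turns the whole filter off. Weights are
normalized over the full fitted set; variable importance is the summed
weight of containing models; among near-best models (ΔAIC < 2) the
final choice maximizes the summed importance of its *distinguishing*
variables (those not shared by all near-best models), then falls back
to smallest AIC. A configurable cap (`max_candidates`, default 12,
i.e. at most 793 fitted models) bounds the stage; the enumerator itself
streams combinations and has been checked against the closed-form
binomial sum up to the 24 157 combinations of 28 candidates.

### 1.5 Prediction and extrapolation

Daily maps evaluate the chosen model on every grid cell with lag-shifted
covariates; lag-infeasible days are skipped with a warning, cells with
missing covariates are masked, not imputed. Extrapolation is
convex-hull membership of each prediction point in the calibration
covariate cloud (Delaunay triangulation; a linear-feasibility fallback
handles degenerate clouds, and one-dimensional spaces reduce to a range
check). Univariate range flags are also available as a cheaper
diagnostic.

### 1.6 Simulation-based validation

A predicted map is converted to an inhomogeneous Poisson point process
at cell resolution: counts `Poisson(λ·cell area)` per cell, points
uniform within the cell (piecewise-constant intensity; sub-cell
interpolation deliberately off). Points are kept within 700 m of the
segment and detected when their perpendicular distance to the track is
at most the ESW. **Geometry choice:** both the corridor and the
detection band are flat-capped rectangles (the along-track projection
must fall inside the segment). Round caps would add `π·ESW²·D` to the
expected count per segment, breaking the closed-form check
`E[count] = 2·ESW·L·D̄` and double-counting points between consecutive
segments of one transect.

Randomness is keyed per (master seed, segment id, cell index), so
per-segment ensembles are independent of iteration order and of the
corridor width (extra cells admitted by a wider corridor only
contribute undetectable points — asserted by exact count equality at
corridors 0.7 vs 5.0 km).

Scores use the sample CRPS,
`mean|xᵢ−y| − ΣᵢΣⱼ|xᵢ−xⱼ|/(2m²)` (the quantile decomposition evaluates
identically on samples), per segment and challenger; the uniform
challenger's level defaults to the pooled CDS density estimate so total
abundance is matched.

## 2. The synthetic study system

The generator produces the statistical structure the analysis assumes,
on an abstract planar km grid (x = 0 is the "coast"; no geodesy, no
bathymetry, no tides).

* **Two water masses and two fronts.** Every field transitions
  logistically from a coastal to an offshore value across a front whose
  cross-shore position drifts offshore through the 134-day season
  (0.55 km/day from 25 km), wobbles sinusoidally in time (9 km, 18-day
  period) and meanders alongshore. Physical fields (temperature,
  salinity, mixed-layer depth, sea-surface height, euphotic depth,
  carbonate variables) ride this physical front; biogeochemical fields
  (chlorophyll, primary production, phytoplankton) ride a *biological*
  front offset 6 km offshore with its own faster wobble (5 km, 11-day
  period). Currents are a weak cross-shore mean flow plus an
  alongshore jet centred on the front, so kinetic-energy covariates
  peak frontally.
* **Three stochastic channels** (all seeded): daily front-position
  jitter per front family (2.5 km physical, 4 km biological),
  spatially coherent day-level anomalies per variable (synoptic
  "weather"), and i.i.d. cell noise; the biogeochemical fields
  additionally carry smoothed mesoscale patchiness (15 km correlation
  length). The day-level channels are what make temporal lags
  identifiable at all: without them, the lagged columns of different
  variables are near-interchangeable spatial gradients and *no* method
  could attribute lags. With all scales at zero the stack equals the
  deterministic template exactly.
* **Truth intensity.** λ(cell, day) = exp(β₀ + Σ effects) with default
  drivers: chlorophyll at lag 7 (Gaussian preference peaking at
  intermediate concentration), mixed-layer depth at lag 10 (saturating
  preference for deep mixing), distance to the chlorophyll front at lag
  2 (dome at ~20 km), and the season-mean distance to the
  mixed-layer-depth front (linear closeness preference, no lag).
  Defaults give mean densities around 0.7 ind km⁻², peaking above 2.
* **Surveys.** Each survey day flies a 4-leg zigzag cut into 5 km
  segments (≈118 segments/day; 26 days by default, ≈2400 good-condition
  segments per world). Individuals arise from the Poisson process
  inside a 0.7 km corridor, are detected with probability
  `exp(−d²/2σ²)` (σ = 0.14 km, which puts the fitted ESW near 0.17 km),
  and detected individuals are grouped into sightings afterwards with
  shifted negative-binomial sizes (configured mean 6.4). Beaufort
  (0–5) and subjective (poor–excellent) conditions are drawn
  independently per segment; the analysis keeps Beaufort ≤ 3 and
  subjective ≥ medium.

**What the generator does not emulate** — and hence what green tests do
not establish about field data: real bathymetric structure and geodesic
geometry; temporally autocorrelated (rather than i.i.d.) synoptic
anomalies; spatial clustering of individuals (the point process is
Poisson in individuals, so realized group sizes on the sighting table
are availability-truncated far below the configured mean at these
densities — the configured group-size distribution only bites at high
intensity); observation conditions correlated with the environment; and
responsive movement (animals here re-equilibrate to the lagged field
instantly). Passing tests show the *estimators* recover a truth of the
assumed form, not that the assumed form is right for any particular
ecosystem.

## 3. Problem sizes and determinism

Default test/acceptance scales, chosen to exercise every code path at
desk scale: one synthetic winter of 134 days on a 30×20 grid of 5 km
cells; ~2400 good segments per world; 20 replicate worlds for lag
recovery; 200 replicates (n = 300 distances) for CI coverage; 50
replicate surveys for density recovery; 100-iteration scoring over the
full segment set; ≤ 793 models in the combination stage (the 24 157
figure is verified in the enumerator without fitting). Every stochastic
stage takes an explicit seed and every configuration object round-trips
through YAML, so any artifact is regenerable from configuration + seed.

## 4. Known limitations and open choices

* The quantile-saturation bounds are inner order statistics rather than
  interpolated quantiles: interpolated bounds drift under re-clipping,
  and exact idempotence was judged worth the (sub-observation-spacing)
  difference.
* The smoothing parameter is shared across terms of one model;
  per-term selection would need a multidimensional search for little
  benefit at basis dimension 4.
* AIC for penalized fits uses total edf; alternative conditional/
  corrected AICs would shift all models in a set similarly, and the
  procedures here only consume AIC *differences* within a set.
* The daily-density SE per stratum assumes independent segments;
  transect-level clustering of effort is not modelled.
* Front detection is gradient-quantile thresholding (default q = 0.90,
  at-or-above, positive gradients only); the operator and threshold are
  exposed because front-detection conventions differ between tools.
* A low-intensity world makes the group-size model nearly inert (see
  §2); raising β₀ restores it, at the cost of unrealistically dense
  surveys.
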