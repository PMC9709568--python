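# laggedsdm

Lag-resolved species distribution modelling for segmented line-transect
surveys: conventional distance sampling, Tweedie spline habitat models
fitted against environmental covariates at a set of temporal lags,
exhaustive AIC-weight model selection, daily density prediction with
convex-hull extrapolation diagnostics, and a simulation-based proper
scoring of predicted maps against the realized survey — plus a
synthetic generator of frontal ocean fields and zigzag aerial surveys
that makes the whole chain testable end to end without any data
download.

The target use case is the one faced by marine megafauna ecologists in
winter shelf seas: a mobile predator (here, common dolphins over a
coastal–shelf front system) tracks oceanographic structures with a
delay that depends on how far up the trophic chain the signal has to
propagate. Repeated aerial surveys give counts per 5 km effort
segment; daily ocean model fields give the candidate drivers. The
question is *which* variables and *at which lag* (0, 1, 2, 4, 7, 10 or
30 days) best explain the day-to-day distribution, and whether the
resulting daily maps predict better than static alternatives.

## The model

**Detection.** Perpendicular sighting distances, right-truncated at
w = 0.4 km, are fitted by maximum likelihood with half-normal
g(x) = exp(−x²/2σ²) or hazard-rate g(x) = 1 − exp(−(x/σ)^−b) detection
functions, compared by AIC. The effective strip half-width is
ESW = ∫₀ʷ g(x) dx, and density per stratum is

    D̂ = Σ sᵢ / (2 · ESW · Σ Lᵢ),

with a variance combining the among-segment encounter-rate variance and
the ESW variance (delta method).

**Habitat model.** Counts of individuals per segment are modelled as
Tweedie (power 1 < p < 2, log link) with the effectively sampled area as
offset:

    E[yᵢ] = exp( log(2·ESW·Lᵢ) + β₀ + Σⱼ fⱼ(x_{ij}) ),

where each fⱼ is a cubic spline with basis dimension 4, centred and
penalized on its curvature; smoothing is selected by GCV and the
Tweedie log-likelihood (hence AIC) is evaluated exactly with the
Dunn–Smyth series. For every dynamic variable, one model per lag plus
a null model are ranked by Akaike weight wᵢ = exp(−Δᵢ/2)/Σexp(−Δⱼ/2);
lags with ΔAIC < 2 are retained, and variables whose best lag carries
less than 50% weight (or that fail to beat the null) are discarded.
Every combination of up to four surviving (variable, lag) candidates
with pairwise |r| ≤ 0.6 is then fitted; variable importance is the
summed weight of the models containing each variable.

**Validation.** Each predicted map is treated as the intensity of an
inhomogeneous Poisson point process; simulated individuals within 700 m
of a surveyed segment are "detected" when their perpendicular track
distance is at most the ESW, and the ensemble of 100 simulated counts
per segment is scored against the observed count with the sample-based
continuous ranked probability score (CRPS; lower is better). Three
challengers are compared: day-matched daily maps, one seasonal map, and
a spatially uniform density.

## Worked example

```python
from laggedsdm import config, distance, lags, pipeline, survey, synthetic

cfg = config.PipelineConfig()          # the default synthetic study
cfg.env.seed = 1
env = pipeline.prepare_environment(cfg)
truth = synthetic.generate_truth_density(env, cfg.truth)
segments, sightings = synthetic.simulate_survey(
    truth, cfg.design, cfg.truth, seed=10001, env_config=cfg.env)

good_seg, good_sgt = survey.filter_good_conditions(segments, sightings)
det = distance.fit_detection(good_sgt["perp_distance_km"], "auto", 0.4)
print(det.key, round(det.sigma, 3), round(det.esw, 3))

cov = pipeline.build_covariate_table(env, good_seg, good_sgt, det.esw, cfg)
print(lags.screen_lags(cov, "Chl").table["weight"].round(3))
```

This prints a half-normal fit with `hn 0.138 0.172` — the detection
scale σ̂ = 0.138 km against a simulated truth of 0.140 km, and an
effective strip half-width of 0.172 km (95% CI 0.166–0.178) — and a
lag-competition table for chlorophyll in which the 7-day-lag model
carries an Akaike weight of 1.000 (all other lags and the null model
round to 0.000), recovering the 7-day delay built into the truth
surface. The pooled density estimate on the same run is
0.672 ± 0.019 individuals km⁻² against a truth-surface mean of 0.709.

The same chain is available from the shell:

```bash
laggedsdm run-all --out results/run --seed 1
```

which writes the detection fit, per-day densities, the lag-screen
matrix, the selection and importance tables, daily prediction maps
(NetCDF), the CRPS score table and a JSON report.

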