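"""End-to-end orchestration: simulate -> features -> CDS -> lag screening
-> model selection -> daily prediction -> simulation-based validation.

Every stage is a thin call into the corresponding module; the result is
a report dictionary (and, optionally, a directory of CSV/JSON/NetCDF
artifacts) regenerable from configuration + seed alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import distance, features, gam, lags, prediction, selection, survey, synthetic, validation
from .config import PipelineConfig

logger = logging.getLogger(__name__)

#: Day-varying fields offered to the lag competition.
DYNAMIC_VARIABLES = (
    "Temp", "Salinity", "MLD", "SSH", "Chl", "NPP", "Phyto", "ZEu", "DissIC",
    "SPCO2", "CurrentSpeed", "EKE",
    "gradTemp", "gradMLD", "gradSSH", "gradSal", "gradNPP", "gradChl",
    "dist_front_Temp", "dist_front_MLD", "dist_front_NPP", "dist_front_Chl",
)
#: Season-scale fields screened against the null only.
STATIC_VARIABLES = (
    "mean_dist_front_Temp", "mean_dist_front_MLD", "mean_dist_front_NPP",
    "mean_dist_front_Chl",
    "persistence_front_Temp", "persistence_front_MLD", "persistence_front_NPP",
    "persistence_front_Chl",
)


def prepare_environment(config: PipelineConfig) -> xr.Dataset:
    """Raw fields plus derived dynamics plus front features."""
    env = synthetic.generate_env_series(config.env)
    env = features.derive_dynamic_fields(env)
    env = features.add_front_features(env, config.front_quantile)
    return env


def build_covariate_table(env: xr.Dataset, segments: pd.DataFrame,
                          sightings: pd.DataFrame, esw: float,
                          config: PipelineConfig,
                          dynamic=DYNAMIC_VARIABLES, static=STATIC_VARIABLES) -> pd.DataFrame:
    """Lagged, saturated covariates with the response and effort offset."""
    dynamic = [v for v in dynamic if v in env]
    static = [v for v in static if v in env]
    table = features.extract_at_segments(env, segments, config.lags, list(dynamic) + list(static))
    lo, hi = config.saturation
    for col in table.columns:
        if col in ("segment_id", "day", "length_km"):
            continue
        table[col] = features.saturate_quantiles(table[col].values, lo, hi)
    return table.assign(
        n_individuals=survey.counts_per_segment(segments, sightings).values,
        offset_area_km2=2.0 * esw * table["length_km"].values,
    )


def run_all(config: PipelineConfig, out_dir=None,
            n_validation_days: int | None = None) -> dict:
    """Run the whole pipeline; return the report dictionary.

    ``n_validation_days`` caps the number of survey days entering the
    simulation-based scoring stage (all days when None).
    """
    rng_seed = config.seed
    report: dict = {"seed": rng_seed}

    logger.info("stage 1: synthetic environment and truth")
    env = prepare_environment(config)
    density_truth = synthetic.generate_truth_density(env, config.truth, config.front_quantile)
    report["truth_days"] = [int(density_truth.day.values[0]), int(density_truth.day.values[-1])]

    logger.info("stage 2: survey simulation")
    segments, sightings = synthetic.simulate_survey(
        density_truth, config.design, config.truth, seed=rng_seed, env_config=config.env
    )
    good_segments, good_sightings = survey.filter_good_conditions(
        segments, sightings, config.max_beaufort, config.min_subjective
    )
    effort = survey.summarize_effort(segments, sightings, "day",
                                     config.max_beaufort, config.min_subjective)
    report["n_segments"] = len(segments)
    report["n_good_segments"] = len(good_segments)
    report["n_sightings_good"] = len(good_sightings)

    logger.info("stage 3: distance sampling")
    det = distance.fit_detection(
        good_sightings["perp_distance_km"].values, config.detection_key, config.truncation_km
    )
    dens_by_day = distance.estimate_density(good_segments, good_sightings, det, "day")
    dens_pooled = distance.estimate_density(good_segments, good_sightings, det)[0]
    report["detection"] = det.to_dict()
    report["density_pooled"] = asdict(dens_pooled)

    logger.info("stage 4: covariates and lag screening")
    covariates = build_covariate_table(env, good_segments, good_sightings, det.esw, config)
    screen_results = []
    power = None
    for var in DYNAMIC_VARIABLES:
        if var not in env:
            continue
        res = lags.screen_lags(covariates, var, config.lags, power=power)
        power = res.power
        screen_results.append(res)
    for var in STATIC_VARIABLES:
        if var not in env:
            continue
        screen_results.append(lags.screen_static(covariates, var, power=power))
    candidates = lags.preselect_variables(screen_results)
    weight_of = {
        (r.variable, lag): float(r.table.loc[lag, "weight"])
        for r in screen_results for lag in r.retained_lags
    }
    candidates = sorted(candidates, key=lambda c: -weight_of.get(c, 0.0))
    if len(candidates) > config.max_candidates:
        candidates = candidates[: config.max_candidates]
    report["screen_weights"] = {
        r.variable: {str(k): float(v) for k, v in r.table["weight"].items()}
        for r in screen_results
    }
    report["candidates"] = [list(c) for c in candidates]

    logger.info("stage 5: exhaustive model selection over %d candidates", len(candidates))
    combos = selection.enumerate_candidates(
        candidates, covariates, config.max_model_size, config.cor_threshold
    )
    sel = selection.select_best(covariates, combos, power=power)
    best = sel.chosen_model
    report["n_models_fitted"] = len(sel.table)
    report["chosen_model"] = {
        "terms": best.term_names(), "aic": best.aic,
        "explained_deviance": best.explained_deviance, "edf": best.edf_total,
        "tweedie_power": best.power,
    }
    report["importance"] = sel.importance.to_dict("records")

    logger.info("stage 6: daily prediction")
    max_lag = max((int(t.name.rpartition("_lag")[2]) for t in best.terms), default=0)
    first_day = int(env.day.values[0]) + max_lag
    pred_days = [int(d) for d in env.day.values if d >= first_day]
    maps, daily_series = prediction.predict_daily(best, env, pred_days, calibration=covariates)
    report["daily_series"] = daily_series.to_dict("records")

    logger.info("stage 7: seasonal challenger")
    seasonal_fields = features.seasonal_summaries(env, [v for v in DYNAMIC_VARIABLES if v in env])
    seasonal_candidates = [(v, 0) for v in seasonal_fields.data_vars]
    seas_table = build_covariate_table(
        seasonal_fields, good_segments, good_sightings, det.esw, config,
        dynamic=(), static=tuple(seasonal_fields.data_vars),
    )
    screened_seasonal = []
    for var, _ in seasonal_candidates:
        res = lags.screen_static(seas_table, var, power=power)
        if res.retained:
            screened_seasonal.append(((var, 0), float(res.table.loc[0, "weight"])))
    screened_seasonal.sort(key=lambda t: -t[1])
    seasonal_cands = [c for c, _ in screened_seasonal[: config.max_candidates]]
    if not seasonal_cands:
        seasonal_cands = seasonal_candidates[: config.max_candidates]
    seas_sel = selection.fit_seasonal_model(
        seas_table, seasonal_cands, max_size=config.max_model_size,
        cor_threshold=config.cor_threshold, power=power,
    )
    seasonal_model = seas_sel.chosen_model
    report["seasonal_model"] = {
        "terms": seasonal_model.term_names(),
        "explained_deviance": seasonal_model.explained_deviance,
    }
    seas_pairs = [(t.name.rpartition("_lag")[0], 0) for t in seasonal_model.terms]
    seas_cells = features.extract_at_cells(seasonal_fields, int(env.day.values[-1]), seas_pairs)
    seas_mu = seasonal_model.predict(seas_cells)
    seasonal_map = xr.DataArray(
        seas_mu.reshape(env.sizes["y"], env.sizes["x"]),
        coords={"y": env.y.values, "x": env.x.values}, dims=("y", "x"),
        attrs={"cell_km": features.cell_km_of(env)},
    )

    logger.info("stage 8: simulation-based validation")
    uniform_map = validation.build_uniform_map(env, dens_pooled.density)
    val_days = sorted(good_segments["day"].unique())
    if n_validation_days is not None:
        val_days = val_days[:n_validation_days]
    val_segments = good_segments[good_segments["day"].isin(val_days)]
    scores = validation.score_models(
        maps["density"], seasonal_map, uniform_map, val_segments, good_sightings,
        det.esw, n_iter=config.n_validation_iter, seed=rng_seed,
    )
    report["score_summary"] = scores.summary().to_dict("records")

    if out_dir is not None:
        _write_outputs(Path(out_dir), report, env, segments, sightings, effort, det,
                       dens_by_day, covariates, screen_results, sel, maps,
                       daily_series, scores)
    report["_artifacts"] = {
        "environment": env, "density_truth": density_truth,
        "segments": segments, "sightings": sightings,
        "covariates": covariates, "detection": det,
        "screen_results": screen_results, "selection": sel,
        "maps": maps, "seasonal_map": seasonal_map, "scores": scores,
    }
    return report


def _write_outputs(out, report, env, segments, sightings, effort, det, dens_by_day,
                   covariates, screen_results, sel, maps, daily_series, scores) -> None:
    out.mkdir(parents=True, exist_ok=True)
    synthetic.write_survey_csv(segments, sightings, out)
    effort.to_csv(out / "effort_summary.csv", index=False)
    with open(out / "detection.json", "w") as fh:
        json.dump(det.to_dict(), fh, indent=2)
    pd.DataFrame([asdict(d) for d in dens_by_day]).to_csv(out / "densities.csv", index=False)
    covariates.to_csv(out / "covariates.csv", index=False)
    lags.screen_matrix(screen_results).to_csv(out / "lag_screen.csv")
    sel.table.drop(columns=["variables"]).to_csv(out / "selection.csv", index=False)
    sel.importance.to_csv(out / "importance.csv", index=False)
    with open(out / "best_model.json", "w") as fh:
        fh.write(sel.chosen_model.to_json())
    daily_series.to_csv(out / "daily_series.csv", index=False)
    maps.to_netcdf(out / "daily_maps.nc", engine="scipy")
    scores.scores.to_csv(out / "scores.csv", index=False)
    validation.plot_score_densities(scores, out / "score_densities.png")
    clean = {k: v for k, v in report.items() if k != "_artifacts"}
    with open(out / "report.json", "w") as fh:
        json.dump(clean, fh, indent=2, default=str)
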