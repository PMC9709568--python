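"""Shared fixtures: a small, fast synthetic scene and its survey."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from laggedsdm import config as cfgmod
from laggedsdm import distance, pipeline, survey, synthetic


def small_env_config(seed: int = 0, **overrides) -> cfgmod.EnvConfig:
    base = dict(nx=14, ny=10, cell_km=5.0, day_start=1, day_end=70,
                front_start_km=15.0, front_drift_km_day=0.5, seed=seed)
    base.update(overrides)
    return cfgmod.EnvConfig(**base)


def zero_noise_config(seed: int = 0) -> cfgmod.EnvConfig:
    cfg = small_env_config(seed=seed, front_jitter_sd_km=0.0, bio_front_jitter_sd_km=0.0,
                           u_noise_sd=0.0, v_noise_sd=0.0)
    for tpl in cfg.variables.values():
        tpl.noise_sd = 0.0
        tpl.day_sd = 0.0
        tpl.patch_sd = 0.0
    return cfg


def small_design(**overrides) -> cfgmod.SurveyDesign:
    base = dict(survey_days=tuple(range(32, 70, 6)), n_legs=3)
    base.update(overrides)
    return cfgmod.SurveyDesign(**base)


@pytest.fixture(scope="session")
def small_env():
    return synthetic.generate_env_series(small_env_config())


@pytest.fixture(scope="session")
def small_scene():
    """Environment, truth density and a simulated survey at small scale."""
    cfg = cfgmod.PipelineConfig(env=small_env_config(), design=small_design())
    env = pipeline.prepare_environment(cfg)
    density = synthetic.generate_truth_density(env, cfg.truth)
    segments, sightings = synthetic.simulate_survey(
        density, cfg.design, cfg.truth, seed=11, env_config=cfg.env
    )
    return {
        "config": cfg, "env": env, "density": density,
        "segments": segments, "sightings": sightings,
    }


@pytest.fixture(scope="session")
def small_covariates(small_scene):
    cfg = small_scene["config"]
    good_seg, good_sgt = survey.filter_good_conditions(
        small_scene["segments"], small_scene["sightings"]
    )
    det = distance.fit_detection(good_sgt["perp_distance_km"].values, "hn", cfg.truncation_km)
    table = pipeline.build_covariate_table(
        small_scene["env"], good_seg, good_sgt, det.esw, cfg
    )
    return {"table": table, "detection": det, "segments": good_seg, "sightings": good_sgt}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def poisson_count_frame(rng, n=400, effect=None, seed_cols=("x",)):
    """Simple count data with known log-linear structure for GAM tests."""
    x = rng.uniform(0, 6, n)
    area = rng.uniform(0.5, 2.0, n)
    eta = np.log(area) + (effect(x) if effect is not None else 0.0)
    y = rng.poisson(np.exp(eta)).astype(float)
    return pd.DataFrame({"x": x, "n_individuals": y, "offset_area_km2": area})
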