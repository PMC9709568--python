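"""Synthetic ocean, known-truth dolphin intensity, and simulated surveys.

The generator emulates the statistical structure the downstream analysis
assumes, on an abstract planar km grid:

* two water masses (coastal vs shelf) separated by a sharp mixed-layer
  front whose cross-shore position drifts offshore through the season,
  wobbles sinusoidally in time and meanders alongshore;
* a daily dolphin intensity surface driven by *lagged* covariates
  (chlorophyll 7 d back, mixed-layer depth 10 d back, distance to the
  chlorophyll front 2 d back, season-mean distance to the MLD front);
* zigzag line-transect surveys cut into 5 km segments, an individual-level
  Poisson point process in a detection corridor, half-normal detection
  by perpendicular distance, and per-segment observation conditions.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import expit

from . import features
from .config import ConfigurationError, EnvConfig, SurveyDesign, TruthParams

BEAUFORT_LEVELS = (0, 1, 2, 3, 4, 5)
SUBJECTIVE_LEVELS = ("poor", "medium", "good", "excellent")


# ---------------------------------------------------------------------------
# environmental fields


def front_position(config: EnvConfig, day, y_km, front: str = "physical"):
    """Deterministic cross-shore front position (km) for day(s) and y.

    The physical front drifts offshore with a slow temporal wobble and an
    alongshore meander; the biological front trails it offshore with its
    own, faster wobble.  Daily stochastic jitter is added on top by the
    generator and is not part of this trajectory.
    """
    day = np.asarray(day, dtype=float)
    y = np.asarray(y_km, dtype=float)
    t = day - config.day_start
    xf = (
        config.front_start_km
        + config.front_drift_km_day * t
        + config.front_wobble_amp_km * np.sin(2 * np.pi * t / config.front_wobble_period_d)
    )
    if front == "biological":
        xf = xf + config.bio_front_offset_km + config.bio_front_wobble_amp_km * np.sin(
            2 * np.pi * t / config.bio_front_wobble_period_d + config.bio_front_wobble_phase
        )
    elif front != "physical":
        raise ConfigurationError(f"unknown front family {front!r}")
    meander = config.front_sinuosity_amp_km * np.sin(
        2 * np.pi * y / config.front_sinuosity_wavelength_km
        + 2 * np.pi * t / config.front_sinuosity_period_d
    )
    return xf + meander


def _cross_front_field(config: EnvConfig, tpl, xf_rows: np.ndarray) -> np.ndarray:
    x = (np.arange(config.nx) + 0.5) * config.cell_km
    xx = np.broadcast_to(x, (config.ny, config.nx))
    cross = expit((xx - xf_rows[:, None]) / (tpl.width_km / 4.0))
    return tpl.coastal + (tpl.offshore - tpl.coastal) * cross + tpl.trend_per_km * xx


def template_field(config: EnvConfig, variable: str, day: int) -> np.ndarray:
    """Noise-free field for one variable and day (the deterministic template)."""
    tpl = config.variables[variable]
    y = (np.arange(config.ny) + 0.5) * config.cell_km
    return _cross_front_field(config, tpl, front_position(config, day, y, tpl.front))


def _velocity_templates(config: EnvConfig, xf_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = (np.arange(config.nx) + 0.5) * config.cell_km
    xx = np.broadcast_to(x, (config.ny, config.nx))
    u = np.full((config.ny, config.nx), config.u_mean)
    v = config.jet_amp * np.exp(-((xx - xf_rows[:, None]) ** 2) / (2.0 * config.jet_width_km**2))
    return u, v


def generate_env_series(config: EnvConfig) -> xr.Dataset:
    """Daily raster stack for all twelve raw variables.

    Fields are smooth within each water mass with a sharp cross-front
    transition.  Three seeded stochastic layers sit on the deterministic
    template: daily front-position jitter (per front family), a
    spatially coherent day anomaly per variable, and i.i.d. cell noise.
    With all noise scales at zero the stack equals the template exactly.
    """
    days = np.array(list(config.days))
    n_days = len(days)
    rng = np.random.default_rng(config.seed)
    x = (np.arange(config.nx) + 0.5) * config.cell_km
    y = (np.arange(config.ny) + 0.5) * config.cell_km
    coords = {"day": days, "y": y, "x": x}
    shape = (n_days, config.ny, config.nx)
    ds = xr.Dataset(coords=coords, attrs={"cell_km": config.cell_km})
    jitter = {
        "physical": rng.normal(0.0, config.front_jitter_sd_km, n_days)
        if config.front_jitter_sd_km > 0 else np.zeros(n_days),
        "biological": rng.normal(0.0, config.bio_front_jitter_sd_km, n_days)
        if config.bio_front_jitter_sd_km > 0 else np.zeros(n_days),
    }
    for var, tpl in config.variables.items():
        data = np.empty(shape)
        day_anom = (rng.normal(0.0, tpl.day_sd, n_days) if tpl.day_sd > 0
                    else np.zeros(n_days))
        for i, d in enumerate(days):
            xf = front_position(config, d, y, tpl.front) + jitter[tpl.front][i]
            data[i] = _cross_front_field(config, tpl, xf) + day_anom[i]
        if tpl.patch_sd > 0:
            # mesoscale patchiness: smoothed white noise, re-normalized to
            # unit sd, so the configured amplitude is the realized one
            from scipy.ndimage import gaussian_filter

            sigma_cells = tpl.patch_scale_km / config.cell_km
            for i in range(n_days):
                blob = gaussian_filter(rng.standard_normal((config.ny, config.nx)),
                                       sigma_cells, mode="nearest")
                sd = blob.std()
                if sd > 0:
                    data[i] += tpl.patch_sd * blob / sd
        if tpl.noise_sd > 0:
            data = data + rng.normal(0.0, tpl.noise_sd, size=shape)
        ds[var] = (("day", "y", "x"), data)
    u = np.empty(shape)
    v = np.empty(shape)
    for i, d in enumerate(days):
        xf = front_position(config, d, y, "physical") + jitter["physical"][i]
        u[i], v[i] = _velocity_templates(config, xf)
    if config.u_noise_sd > 0:
        u = u + rng.normal(0.0, config.u_noise_sd, size=shape)
    if config.v_noise_sd > 0:
        v = v + rng.normal(0.0, config.v_noise_sd, size=shape)
    ds["U"] = (("day", "y", "x"), u)
    ds["V"] = (("day", "y", "x"), v)
    return ds


# ---------------------------------------------------------------------------
# truth intensity


def prepare_truth_covariates(env: xr.Dataset, params: TruthParams,
                             front_quantile: float = 0.90) -> xr.Dataset:
    """Attach the derived covariates the truth effects refer to."""
    needed = {e.variable for e in params.effects}
    front_vars = sorted({
        v.replace("dist_front_", "").replace("mean_", "").replace("persistence_front_", "")
        for v in needed - set(env.data_vars)
        if v.startswith(("dist_front_", "mean_dist_front_", "persistence_front_"))
    })
    out = env
    if front_vars:
        out = features.add_front_features(env, front_quantile, tuple(front_vars))
    missing = needed - set(out.data_vars)
    if missing:
        raise ConfigurationError(f"truth effects refer to unknown fields: {sorted(missing)}")
    return out


def generate_truth_density(env: xr.Dataset, params: TruthParams,
                           front_quantile: float = 0.90) -> xr.DataArray:
    """Daily intensity lambda(cell, day) = exp(b0 + sum of lagged effects).

    Defined only for days late enough that every lag is representable;
    requesting earlier days is impossible by construction (the output
    simply starts at first_day + max_lag).
    """
    env = prepare_truth_covariates(env, params, front_quantile)
    days = env["day"].values.astype(int)
    start = int(days[0]) + params.max_lag
    out_days = days[days >= start]
    if out_days.size == 0:
        raise ConfigurationError(
            f"date range too short: no day at or after {start} supports the max lag"
        )
    log_lam = np.full((len(out_days), env.sizes["y"], env.sizes["x"]), params.intercept)
    for i, d in enumerate(out_days):
        for eff in params.effects:
            da = env[eff.variable]
            layer = da.values if "day" not in da.dims else da.sel(day=d - eff.lag).values
            log_lam[i] += eff(layer)
    da = xr.DataArray(
        np.exp(log_lam),
        coords={"day": out_days, "y": env["y"].values, "x": env["x"].values},
        dims=("day", "y", "x"),
        name="density",
    )
    da.attrs["cell_km"] = features.cell_km_of(env)
    return da


def density_on_day(density: xr.DataArray, day: int) -> xr.DataArray:
    if int(day) not in density["day"].values.astype(int):
        raise ConfigurationError(
            f"day {day} is earlier than the first lag-feasible day "
            f"{int(density['day'].values[0])}"
        )
    return density.sel(day=int(day))


def total_abundance(density: xr.DataArray) -> xr.DataArray:
    """Area-integrated expected abundance per day (sum of lambda x cell area)."""
    cell = features.cell_km_of(density)
    return density.sum(("y", "x")) * cell**2


# ---------------------------------------------------------------------------
# survey simulation


def zigzag_segments(config: EnvConfig, design: SurveyDesign, day: int,
                    id_offset: int = 0) -> pd.DataFrame:
    """Segment endpoints for one survey day's zigzag track.

    Legs run diagonally between the offshore margins while sweeping the
    alongshore axis; the sweep origin rotates with the day so successive
    survey days do not retrace the same track.
    """
    lx = config.nx * config.cell_km
    ly = config.ny * config.cell_km
    x0, x1 = design.margin_km, lx - design.margin_km
    phase = (day % 7) / 7.0 * (ly - 2 * design.margin_km) / max(design.n_legs, 1)
    ys = np.linspace(design.margin_km, ly - design.margin_km, design.n_legs + 1)
    ys = design.margin_km + (ys - design.margin_km + phase) % (ly - 2 * design.margin_km)
    waypoints = [((x0 if i % 2 == 0 else x1), yv) for i, yv in enumerate(ys)]
    rows = []
    seg_id = id_offset
    for (xa, ya), (xb, yb) in zip(waypoints[:-1], waypoints[1:]):
        leg = np.hypot(xb - xa, yb - ya)
        n_seg = int(leg // design.segment_km)
        for j in range(n_seg):
            f0 = j * design.segment_km / leg
            f1 = (j + 1) * design.segment_km / leg
            rows.append({
                "segment_id": seg_id,
                "day": int(day),
                "x_start": xa + f0 * (xb - xa),
                "y_start": ya + f0 * (yb - ya),
                "x_end": xa + f1 * (xb - xa),
                "y_end": ya + f1 * (yb - ya),
                "length_km": design.segment_km,
            })
            seg_id += 1
    return pd.DataFrame(rows)


def _group_sizes(rng: np.random.Generator, n_individuals: int, params: TruthParams) -> list[int]:
    """Partition detected individuals into sightings (shifted neg-binomial)."""
    sizes: list[int] = []
    remaining = n_individuals
    mean_extra = max(params.group_mean - 1.0, 1e-9)
    shape = params.group_size_shape
    p = shape / (shape + mean_extra)
    while remaining > 0:
        g = 1 + int(rng.negative_binomial(shape, p))
        g = min(g, remaining)
        sizes.append(g)
        remaining -= g
    return sizes


def simulate_survey(density: xr.DataArray, design: SurveyDesign, params: TruthParams,
                    seed: int, env_config: EnvConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate zigzag surveys over a known intensity surface.

    Individuals arise from a Poisson point process with the given daily
    intensity inside a corridor of half-width ``corridor_km`` around each
    segment; each individual is detected with probability
    exp(-d^2 / (2 sigma_true^2)) where d is its perpendicular distance.
    Detected individuals are grouped into sightings afterwards, so the
    point-process units are individuals, not groups.

    Returns (segments, sightings) tables.
    """
    if params.sigma_true_km <= 0:
        raise ConfigurationError("sigma_true must be positive")
    cell = features.cell_km_of(density)
    if env_config is None:
        env_config = EnvConfig(
            nx=density.sizes["x"], ny=density.sizes["y"], cell_km=cell,
            day_start=int(density.day.values[0]), day_end=int(density.day.values[-1]),
        )
    rng = np.random.default_rng(seed)
    avail_days = set(density["day"].values.astype(int))
    seg_frames = []
    sight_rows = []
    seg_id = 0
    w = design.corridor_km
    sigma = params.sigma_true_km
    for day in design.survey_days:
        if int(day) not in avail_days:
            raise ConfigurationError(f"survey day {day} outside the density date range")
        segs = zigzag_segments(env_config, design, int(day), id_offset=seg_id)
        seg_id += len(segs)
        lam = density.sel(day=int(day)).values
        for row in segs.itertuples(index=False):
            n_steps = max(int(round(row.length_km / design.step_km)), 1)
            fr = (np.arange(n_steps) + 0.5) / n_steps
            mx = row.x_start + fr * (row.x_end - row.x_start)
            my = row.y_start + fr * (row.y_end - row.y_start)
            ix = np.clip((mx // cell).astype(int), 0, lam.shape[1] - 1)
            iy = np.clip((my // cell).astype(int), 0, lam.shape[0] - 1)
            mu = lam[iy, ix] * (row.length_km / n_steps) * 2.0 * w
            n_ind = int(rng.poisson(mu).sum())
            if n_ind == 0:
                continue
            d = rng.uniform(0.0, w, size=n_ind)
            detected = d[rng.random(n_ind) < np.exp(-(d**2) / (2.0 * sigma**2))]
            if detected.size == 0:
                continue
            start = 0
            for g in _group_sizes(rng, detected.size, params):
                sight_rows.append({
                    "segment_id": row.segment_id,
                    "day": int(day),
                    "perp_distance_km": float(detected[start]),
                    "group_size": int(g),
                })
                start += g
        seg_frames.append(segs)
    segments = pd.concat(seg_frames, ignore_index=True) if seg_frames else pd.DataFrame(
        columns=["segment_id", "day", "x_start", "y_start", "x_end", "y_end", "length_km"]
    )
    n = len(segments)
    segments["beaufort"] = rng.choice(BEAUFORT_LEVELS, size=n, p=list(design.beaufort_probs))
    segments["subjective"] = rng.choice(SUBJECTIVE_LEVELS, size=n, p=list(design.subjective_probs))
    sightings = pd.DataFrame(
        sight_rows, columns=["segment_id", "day", "perp_distance_km", "group_size"]
    )
    return segments, sightings


# ---------------------------------------------------------------------------
# I/O


def write_env_netcdf(env: xr.Dataset, path) -> None:
    """Write the raster stack as (classic) NetCDF."""
    env.to_netcdf(path, engine="scipy")


def read_env_netcdf(path) -> xr.Dataset:
    ds = xr.load_dataset(path, engine="scipy")
    return ds


def write_survey_csv(segments: pd.DataFrame, sightings: pd.DataFrame, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    segments.to_csv(out / "segments.csv", index=False)
    sightings.to_csv(out / "sightings.csv", index=False)
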