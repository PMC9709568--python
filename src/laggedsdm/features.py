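"""Covariate derivation from daily environmental rasters.

Implements the derived oceanographic quantities used by the habitat
models: current speed and eddy kinetic energy from velocity components,
gradient-magnitude maps, gradient-threshold front masks, Euclidean
distance-to-front maps, per-cell front persistence, winter mean/sd
summaries, lagged extraction at segment centroids, and quantile
saturation of outliers.

Conventions (documented because they fix the numbers):
  * gradients are central differences on cell centres (one-sided at the
    grid edge), magnitude sqrt(fx^2 + fy^2), units per km;
  * distances are planar, cell-centre to cell-centre, in km;
  * quantiles are the linear-interpolation (type-7) empirical quantile;
  * a front cell is a cell whose gradient magnitude exceeds that day's
    q-th gradient quantile (default q = 0.90).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

#: Raw fields whose gradient maps are derived.
GRADIENT_VARIABLES = ("Temp", "MLD", "SSH", "Salinity", "NPP", "Chl")
#: Fields for which distance-to-front maps are derived.
FRONT_VARIABLES = ("Temp", "MLD", "NPP", "Chl")

_GRAD_NAME = {"Salinity": "gradSal"}


def gradient_name(variable: str) -> str:
    return _GRAD_NAME.get(variable, f"grad{variable}")


class FeatureError(ValueError):
    pass


def cell_km_of(obj) -> float:
    """Cell size in km, from the attribute or the x-coordinate spacing."""
    if "cell_km" in obj.attrs and obj.attrs["cell_km"] is not None:
        return float(obj.attrs["cell_km"])
    coords = getattr(obj, "coords", {})
    if "x" in coords and obj["x"].size > 1:
        return float(obj["x"].values[1] - obj["x"].values[0])
    raise FeatureError("raster lacks a cell_km attribute and an x coordinate")


def gradient_magnitude(field: np.ndarray, cell_km: float) -> np.ndarray:
    """Gradient-magnitude map (units of field per km) of one 2-D raster."""
    fy, fx = np.gradient(np.asarray(field, dtype=float), cell_km)
    return np.hypot(fx, fy)


def derive_dynamic_fields(env: xr.Dataset) -> xr.Dataset:
    """Add CurrentSpeed, EKE and the six gradient-magnitude stacks.

    CurrentSpeed = sqrt(U^2 + V^2); EKE = 0.5 (U^2 + V^2), so that
    EKE = 0.5 CurrentSpeed^2 cell-wise.
    """
    if "U" not in env or "V" not in env:
        raise FeatureError("velocity components U and V are required")
    cell = cell_km_of(env)
    out = env.copy()
    speed2 = env["U"] ** 2 + env["V"] ** 2
    out["CurrentSpeed"] = np.sqrt(speed2)
    out["EKE"] = 0.5 * speed2
    for var in GRADIENT_VARIABLES:
        if var not in env:
            continue
        grad = np.stack(
            [gradient_magnitude(env[var].isel(day=i).values, cell) for i in range(env.sizes["day"])]
        )
        out[gradient_name(var)] = (("day", "y", "x"), grad)
    return out


@dataclass
class FrontMask:
    """Daily binary front masks derived from one field's gradients."""

    mask: xr.DataArray  # bool, dims (day, y, x)
    source: str
    quantile: float
    thresholds: np.ndarray  # per-day gradient threshold
    degenerate_days: list[int] = field(default_factory=list)  # all-constant days


def detect_fronts(field: xr.DataArray, quantile: float = 0.90, source: str | None = None) -> FrontMask:
    """Flag frontal cells: gradient magnitude at or above the day's
    q-th gradient quantile (and strictly positive, so plateaus never
    count as fronts).

    An all-constant day yields an empty mask and is recorded in
    ``degenerate_days`` (with a warning).
    """
    if not 0 <= quantile < 1 and quantile != 0:
        raise FeatureError("quantile must be in [0, 1)")
    cell = cell_km_of(field)
    days = field["day"].values
    masks = np.zeros(field.shape, dtype=bool)
    thresholds = np.full(len(days), np.nan)
    degenerate: list[int] = []
    for i, d in enumerate(days):
        grad = gradient_magnitude(field.isel(day=i).values, cell)
        if np.allclose(grad, 0.0):
            degenerate.append(int(d))
            continue
        thr = np.quantile(grad, quantile)
        thresholds[i] = thr
        masks[i] = (grad >= thr) & (grad > 0)
    if degenerate:
        warnings.warn(f"constant field on days {degenerate}: empty front mask", stacklevel=2)
    da = xr.DataArray(masks, coords=field.coords, dims=field.dims, name="front")
    da.attrs["cell_km"] = cell
    return FrontMask(da, source or (field.name or "field"), quantile, thresholds, degenerate)


def distance_to_front(mask: FrontMask) -> xr.DataArray:
    """Euclidean distance (km) from each cell centre to the nearest front cell.

    Zero on front cells; all-NaN on days with an empty mask (warned).
    """
    m = mask.mask
    cell = cell_km_of(m)
    out = np.full(m.shape, np.nan)
    empty_days: list[int] = []
    for i, d in enumerate(m["day"].values):
        layer = m.isel(day=i).values
        if not layer.any():
            empty_days.append(int(d))
            continue
        out[i] = ndimage.distance_transform_edt(~layer, sampling=cell)
    if empty_days:
        warnings.warn(f"empty front mask on days {empty_days}: distance undefined", stacklevel=2)
    da = xr.DataArray(out, coords=m.coords, dims=m.dims, name=f"dist_front_{mask.source}")
    da.attrs["cell_km"] = cell
    return da


def front_persistence(mask: FrontMask) -> xr.DataArray:
    """Number of days each cell is frontal across the series."""
    counts = mask.mask.sum("day").astype(int)
    counts.name = f"persistence_front_{mask.source}"
    counts.attrs["cell_km"] = cell_km_of(mask.mask)
    return counts


def add_front_features(env: xr.Dataset, quantile: float = 0.90,
                       variables: tuple[str, ...] = FRONT_VARIABLES) -> xr.Dataset:
    """Attach distance-to-front stacks, their winter means, and persistence.

    Adds, per front variable V: ``dist_front_V`` (daily),
    ``mean_dist_front_V`` (winter-mean raster, static) and
    ``persistence_front_V`` (front-day count raster, static).
    """
    out = env.copy()
    for var in variables:
        if var not in env:
            continue
        fm = detect_fronts(env[var], quantile, source=var)
        dist = distance_to_front(fm)
        out[f"dist_front_{var}"] = dist
        out[f"mean_dist_front_{var}"] = dist.mean("day")
        out[f"persistence_front_{var}"] = front_persistence(fm)
    return out


def seasonal_summaries(env: xr.Dataset, variables: list[str] | None = None) -> xr.Dataset:
    """Winter mean and sd rasters per variable (sd with denominator n-1)."""
    if env.sizes.get("day", 0) < 2:
        raise FeatureError("seasonal sd undefined for fewer than 2 days")
    names = variables if variables is not None else [
        v for v in env.data_vars if "day" in env[v].dims
    ]
    out = xr.Dataset(attrs=dict(env.attrs))
    for v in names:
        out[f"mean_{v}"] = env[v].mean("day")
        out[f"sd_{v}"] = env[v].std("day", ddof=1)
    return out


# ---------------------------------------------------------------------------
# extraction at points


def cell_index(env, x_km, y_km) -> tuple[np.ndarray, np.ndarray]:
    """Grid indices of the cells containing planar points (clipped to grid)."""
    cell = cell_km_of(env)
    ix = np.clip(np.floor(np.asarray(x_km) / cell).astype(int), 0, env.sizes["x"] - 1)
    iy = np.clip(np.floor(np.asarray(y_km) / cell).astype(int), 0, env.sizes["y"] - 1)
    return ix, iy


def column_name(variable: str, lag: int) -> str:
    return f"{variable}_lag{lag}"


def extract_at_segments(env: xr.Dataset, segments: pd.DataFrame,
                        lags, variables: list[str] | None = None) -> pd.DataFrame:
    """Lagged covariate values underlying segment centroids.

    For a segment sampled on day d and lag k, the value is read from the
    day (d - k) raster at the centroid's cell; static rasters (no day
    dimension) are extracted as-is under lag 0.  A (day - lag) earlier
    than the series start raises, naming the segment and lag.
    """
    day_values = env["day"].values if "day" in env.coords else np.array([], dtype=int)
    day_pos = {int(d): i for i, d in enumerate(day_values)}
    if variables is None:
        variables = list(env.data_vars)
    cx = (segments["x_start"].values + segments["x_end"].values) / 2.0
    cy = (segments["y_start"].values + segments["y_end"].values) / 2.0
    ix, iy = cell_index(env, cx, cy)
    days = segments["day"].values.astype(int)
    cols: dict[str, np.ndarray] = {
        "segment_id": segments["segment_id"].values,
        "day": days,
        "length_km": segments["length_km"].values,
    }
    for var in variables:
        da = env[var]
        if "day" not in da.dims:
            cols[column_name(var, 0)] = da.values[iy, ix]
            continue
        values = da.values
        for lag in lags:
            want = days - lag
            missing = [d for d in np.unique(want) if d not in day_pos]
            if missing:
                bad = segments["segment_id"].values[np.isin(want, missing)][0]
                raise FeatureError(
                    f"segment {bad}: day-{lag} lag reaches day {missing[0]}, "
                    "before the start of the environmental series"
                )
            idx = np.array([day_pos[int(d)] for d in want])
            cols[column_name(var, lag)] = values[idx, iy, ix]
    return pd.DataFrame(cols)


def extract_at_cells(env: xr.Dataset, day: int, pairs: list[tuple[str, int]]) -> pd.DataFrame:
    """Covariates for every grid cell on one prediction day.

    ``pairs`` are (variable, lag); static rasters ignore the lag. Raises
    if any required (day - lag) is missing from the series.
    """
    day_values = ([int(d) for d in env["day"].values] if "day" in env.coords else [])
    cols: dict[str, np.ndarray] = {}
    for var, lag in pairs:
        da = env[var]
        if "day" not in da.dims:
            cols[column_name(var, lag)] = da.values.ravel()
            continue
        want = day - lag
        if want not in day_values:
            raise FeatureError(f"day {day} needs lag-{lag} values from day {want}, not in series")
        cols[column_name(var, lag)] = da.sel(day=want).values.ravel()
    n_cells = env.sizes["y"] * env.sizes["x"]
    return pd.DataFrame(cols, index=pd.RangeIndex(n_cells))


def saturate_quantiles(values, lower_q: float = 0.01, upper_q: float = 0.99):
    """Clip values to their empirical [lower_q, upper_q] quantile band.

    The bounds are the inner order statistics (the smallest observation at
    or above the lower quantile position, the largest at or below the
    upper one), so the bounds are actual data values, the operation is
    order-preserving, and re-clipping at the same quantiles of the
    clipped data changes nothing (exact idempotence — interpolated
    quantile conventions drift slightly under repeated clipping).
    """
    if not 0 <= lower_q < upper_q <= 1:
        raise FeatureError("need 0 <= lower_q < upper_q <= 1")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise FeatureError("cannot saturate an empty sample")
    lo = np.quantile(arr, lower_q, method="higher")
    hi = np.quantile(arr, upper_q, method="lower")
    if lo > hi:  # tiny samples with crossing order statistics: no clipping
        return arr.copy()
    return np.clip(arr, lo, hi)
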