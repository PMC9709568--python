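"""Daily density maps, time-series summaries and extrapolation diagnostics.

Predictions are per-km^2 intensities from the chosen habitat model on
every grid cell and day (with delta-method standard errors).  The
extrapolation diagnostic flags prediction points whose covariate vector
falls outside the convex hull of the calibration covariates — the
classic data-envelope criterion for judging whether a prediction is an
interpolation of the fitted relationship or a leap beyond it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr
from scipy.spatial import Delaunay, QhullError

from . import features
from .gam import FittedHabitatModel


class PredictionError(ValueError):
    pass


def _term_pairs(model: FittedHabitatModel) -> list[tuple[str, int]]:
    pairs = []
    for t in model.terms:
        var, _, lag = t.name.rpartition("_lag")
        pairs.append((var, int(lag)))
    return pairs


class Hull:
    """Convex hull of a calibration covariate cloud, queryable many times.

    Membership is decided by Delaunay triangulation of the calibration
    cloud (exact for points in general position); one-dimensional
    covariate spaces reduce to a range check, and degenerate clouds fall
    back to a linear-feasibility test.
    """

    def __init__(self, calibration: pd.DataFrame, covariates: list[str]):
        self.covariates = list(covariates)
        calib = calibration[self.covariates].values.astype(float)
        if calib.shape[0] < calib.shape[1] + 1:
            raise PredictionError(
                f"need at least {calib.shape[1] + 1} calibration points for a "
                f"{calib.shape[1]}-dimensional hull"
            )
        self._calib = calib
        self._tri = None
        if calib.shape[1] > 1:
            try:
                self._tri = Delaunay(calib)
            except QhullError:
                self._tri = None

    def outside(self, prediction: pd.DataFrame) -> np.ndarray:
        """True where a prediction point lies outside the hull."""
        pred = prediction[self.covariates].values.astype(float)
        if self._calib.shape[1] == 1:
            lo, hi = self._calib.min(), self._calib.max()
            return (pred[:, 0] < lo) | (pred[:, 0] > hi)
        if self._tri is not None:
            return self._tri.find_simplex(pred) < 0
        return _hull_flags_lp(self._calib, pred)


def hull_flags(calibration: pd.DataFrame, prediction: pd.DataFrame,
               covariates: list[str]) -> np.ndarray:
    """One-shot convex-hull extrapolation flags (see :class:`Hull`)."""
    return Hull(calibration, covariates).outside(prediction)


def _hull_flags_lp(calib: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Linear-feasibility hull membership (handles degenerate clouds)."""
    from scipy.optimize import linprog

    n = calib.shape[0]
    out = np.zeros(len(pred), dtype=bool)
    a_eq_base = np.vstack([calib.T, np.ones(n)])
    for i, point in enumerate(pred):
        res = linprog(
            c=np.zeros(n), A_eq=a_eq_base, b_eq=np.append(point, 1.0),
            bounds=[(0, None)] * n, method="highs",
        )
        out[i] = not res.success
    return out


def extrapolation_fraction(calibration: pd.DataFrame, prediction: pd.DataFrame,
                           covariates: list[str]) -> tuple[float, np.ndarray]:
    """Share (and per-point flags) of prediction points outside the hull."""
    flags = hull_flags(calibration, prediction, covariates)
    return float(flags.mean()), flags


def range_flags(calibration: pd.DataFrame, prediction: pd.DataFrame,
                covariates: list[str]) -> np.ndarray:
    """Cheaper univariate diagnostic: outside any calibration min/max."""
    out = np.zeros(len(prediction), dtype=bool)
    for c in covariates:
        lo, hi = calibration[c].min(), calibration[c].max()
        out |= (prediction[c].values < lo) | (prediction[c].values > hi)
    return out


def predict_daily(model: FittedHabitatModel, env: xr.Dataset, days,
                  calibration: pd.DataFrame | None = None) -> tuple[xr.Dataset, pd.DataFrame]:
    """Daily density and SE rasters plus a per-day summary table.

    Days whose lags reach before the series start are skipped with a
    warning.  When a calibration table is supplied, per-cell convex-hull
    extrapolation flags and the daily extrapolation fraction are added.
    Cells with missing covariates are masked, not imputed.
    """
    pairs = _term_pairs(model)
    cols = [t.name for t in model.terms]
    ny, nx = env.sizes["y"], env.sizes["x"]
    hull = Hull(calibration, cols) if calibration is not None else None
    kept_days, dens_layers, se_layers, flag_layers, rows = [], [], [], [], []
    for day in days:
        try:
            table = features.extract_at_cells(env, int(day), pairs)
        except features.FeatureError as exc:
            warnings.warn(f"skipping day {day}: {exc}", stacklevel=2)
            continue
        valid = ~table[cols].isna().any(axis=1).values
        mu = np.full(len(table), np.nan)
        se = np.full(len(table), np.nan)
        if valid.any():
            mu_v, se_v = model.predict(table[valid], se=True)
            mu[valid], se[valid] = mu_v, se_v
        kept_days.append(int(day))
        dens_layers.append(mu.reshape(ny, nx))
        se_layers.append(se.reshape(ny, nx))
        row = {
            "day": int(day),
            "mean_density": float(np.nanmean(mu)),
            "var_density": float(np.nanvar(mu)),
            "mean_se": float(np.nanmean(se)),
        }
        if hull is not None:
            flags = np.ones(len(table), dtype=bool)
            flags[valid] = hull.outside(table[valid])
            flag_layers.append(flags.reshape(ny, nx))
            row["extrapolation_fraction"] = float(flags[valid].mean()) if valid.any() else 1.0
        rows.append(row)
    if not kept_days:
        raise PredictionError("no lag-feasible prediction day in the requested range")
    coords = {"day": kept_days, "y": env["y"].values, "x": env["x"].values}
    out = xr.Dataset(coords=coords, attrs={"cell_km": features.cell_km_of(env)})
    out["density"] = (("day", "y", "x"), np.stack(dens_layers))
    out["se"] = (("day", "y", "x"), np.stack(se_layers))
    if calibration is not None:
        out["extrapolation_flag"] = (("day", "y", "x"), np.stack(flag_layers))
    out["winter_mean_density"] = out["density"].mean("day")
    out["winter_var_density"] = out["density"].var("day")
    summary = pd.DataFrame(rows)
    return out, summary
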