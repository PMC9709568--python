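"""Per-variable lag competition against a null model.

For each dynamic variable, one single-smooth model per lag in
{0, 1, 2, 4, 7, 10, 30} plus an intercept-only null model are fitted
(eight models), ranked by AIC, and summarized by delta AIC, Akaike
weight, relative likelihood, RMSE and explained deviance.  Lags with
delta AIC < 2 are retained as the most predictive; a variable is
discarded when its best lag's Akaike weight is below 50% or when the
null model itself sits within delta AIC < 2 of the best lag.  Static
variables are screened against the null only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import LAGS
from .features import column_name
from .gam import FittedHabitatModel, akaike_weights, fit_gam, rmse


class LagScreeningError(ValueError):
    pass


@dataclass
class LagScreenResult:
    """Outcome of the eight-model lag competition for one variable."""

    variable: str
    table: pd.DataFrame          # index: lag (int) or "null"; aic, delta_aic, weight, ...
    retained_lags: list[int]
    retained: bool
    best_lag: int | None         # None when the null model wins outright
    power: float
    static: bool = False


def _fit_table(covariates, columns, labels, response, offset, power) -> tuple[pd.DataFrame, float]:
    rows = []
    for col, label in zip(columns, labels):
        model = fit_gam(covariates, [col] if col else [], response=response,
                        offset=offset, power=power)
        if power is None:
            power = model.power  # profile once, keep fixed across the set
        rows.append({
            "model": label, "aic": model.aic, "rmse": rmse(model),
            "explained_deviance": model.explained_deviance, "edf": model.edf_total,
        })
    table = pd.DataFrame(rows)
    wts = akaike_weights(table["aic"], table["model"])
    table = table.merge(wts[["model", "delta_aic", "rel_likelihood", "weight"]], on="model")
    return table.sort_values("aic", kind="mergesort").reset_index(drop=True), power


def screen_lags(covariates: pd.DataFrame, variable: str, lags=LAGS,
                response: str = "n_individuals", offset: str = "offset_area_km2",
                power: float | None = None, delta_threshold: float = 2.0,
                weight_threshold: float = 0.5) -> LagScreenResult:
    """Fit the per-lag model set for one dynamic variable and apply the
    retention rules.

    The Tweedie power, when not fixed, is profiled on the first lag model
    and then held constant across the eight candidates so their AICs are
    comparable.  Exact AIC ties resolve to the shortest lag (the models
    are ranked by AIC with a stable sort over lags in increasing order).
    """
    cols = [column_name(variable, lag) for lag in lags]
    missing = [c for c in cols if c not in covariates.columns]
    if missing:
        raise LagScreeningError(f"missing lag columns: {missing}")
    table, power = _fit_table(
        covariates, cols + [None], list(lags) + ["null"], response, offset, power
    )
    best = table.iloc[0]["model"]
    close = table[table["delta_aic"] < delta_threshold]["model"].tolist()
    retained_lags = sorted(int(m) for m in close if m != "null")
    null_close = "null" in close
    best_weight = float(table.iloc[0]["weight"])
    retained = (best != "null") and (best_weight >= weight_threshold - 1e-12) and not null_close
    return LagScreenResult(
        variable=variable, table=table.set_index("model"),
        retained_lags=retained_lags, retained=retained,
        best_lag=None if best == "null" else int(best), power=power,
    )


def screen_static(covariates: pd.DataFrame, variable: str,
                  response: str = "n_individuals", offset: str = "offset_area_km2",
                  power: float | None = None, delta_threshold: float = 2.0) -> LagScreenResult:
    """Screen a static (long-term) variable against the null model only.

    Retained iff the variable's model beats the null by at least the
    delta-AIC threshold.
    """
    col = column_name(variable, 0)
    if col not in covariates.columns:
        raise LagScreeningError(f"missing column {col}")
    table, power = _fit_table(covariates, [col, None], [0, "null"], response, offset, power)
    aic_var = float(table.set_index("model").loc[0, "aic"])
    aic_null = float(table.set_index("model").loc["null", "aic"])
    retained = aic_null - aic_var >= delta_threshold
    return LagScreenResult(
        variable=variable, table=table.set_index("model"),
        retained_lags=[0] if retained else [], retained=retained,
        best_lag=0 if aic_var < aic_null else None, power=power, static=True,
    )


def preselect_variables(results: list[LagScreenResult]) -> list[tuple[str, int]]:
    """(variable, lag) candidates surviving the screening rules.

    Every retained lag of a retained variable is carried forward (several
    lags of one variable may coexist in the candidate list, as with
    near-tied lags of an eddy-energy style covariate).
    """
    out: list[tuple[str, int]] = []
    for res in results:
        if not res.retained:
            continue
        for lag in res.retained_lags:
            out.append((res.variable, lag))
    return out


def screen_matrix(results: list[LagScreenResult], value: str = "weight") -> pd.DataFrame:
    """Variable-by-lag matrix of weights (or delta AIC): the lag-competition
    summary grid."""
    rows = {}
    for res in results:
        series = res.table[value].copy()
        series.index = series.index.map(str)
        rows[res.variable] = series
    order = [str(v) for v in (0, 1, 2, 4, 7, 10, 30)] + ["null"]
    out = pd.DataFrame(rows).T
    return out[[c for c in order if c in out.columns]
               + [c for c in out.columns if c not in order]]
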