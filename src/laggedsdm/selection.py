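"""Exhaustive multi-variable model selection with a collinearity cap.

Every combination of up to four pre-selected (variable, lag) candidates
is fitted, excluding combinations containing a pair with |Pearson r|
above the correlation threshold (0.6 by default); two lags of the same
variable never co-occur (they are near-duplicates by construction).
Models are ranked by Akaike weight; per-variable importance is the sum
of the weights of the models containing the variable, and breaks ties
among the near-best (delta AIC < 2) models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .features import column_name
from .gam import FittedHabitatModel, akaike_weights, fit_gam

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


def candidate_column(candidate: tuple[str, int]) -> str:
    return column_name(candidate[0], candidate[1])


def enumerate_candidates(candidates: list[tuple[str, int]], covariates: pd.DataFrame,
                         max_size: int = 4, cor_threshold: float = 0.6,
                         method: str = "pearson") -> list[tuple[tuple[str, int], ...]]:
    """All subsets of 1..max_size mutually compatible candidates.

    A pair is incompatible when the absolute correlation of its covariate
    columns exceeds ``cor_threshold`` (strictly), or when both members are
    lags of the same variable (treated as correlation 1).  A threshold of
    1.0 therefore disables the filter entirely.
    """
    if not candidates:
        raise SelectionError("empty candidate list")
    cols = [candidate_column(c) for c in candidates]
    missing = [c for c in cols if c not in covariates.columns]
    if missing:
        raise SelectionError(f"missing candidate columns: {missing}")
    corr = covariates[cols].corr(method=method).abs().values
    m = len(candidates)
    compatible = corr <= cor_threshold + 1e-12
    for i in range(m):
        for j in range(m):
            if i != j and candidates[i][0] == candidates[j][0]:
                compatible[i, j] = 1.0 <= cor_threshold + 1e-12
    out = []
    for size in range(1, max_size + 1):
        for idx in combinations(range(m), size):
            if all(compatible[a, b] for a, b in combinations(idx, 2)):
                out.append(tuple(candidates[i] for i in idx))
    return out


@dataclass
class SelectionResult:
    """Outcome of the exhaustive combination competition."""

    table: pd.DataFrame            # model_id, variables, aic, delta_aic, weight, ...
    importance: pd.DataFrame       # variable, importance, rank
    best_ids: list[int]            # delta AIC < 2 set
    chosen_id: int
    chosen_model: FittedHabitatModel
    power: float


def _model_label(combo) -> str:
    return " + ".join(candidate_column(c) for c in combo)


def select_best(covariates: pd.DataFrame, combos: list[tuple[tuple[str, int], ...]],
                response: str = "n_individuals", offset: str = "offset_area_km2",
                power: float | None = None, delta_threshold: float = 2.0) -> SelectionResult:
    """Fit every combination, rank by Akaike weight, pick the final model.

    Individual fit failures are logged and excluded (not fatal).  Among
    the delta AIC < 2 near-best models, the final model is the one whose
    distinguishing variables (those not shared by all near-best models)
    carry the largest summed-weight importance; remaining ties resolve to
    the smallest AIC.
    """
    if not combos:
        raise SelectionError("no candidate combinations to fit")
    rows = []
    failures = []
    for i, combo in enumerate(combos):
        cols = [candidate_column(c) for c in combo]
        try:
            model = fit_gam(covariates, cols, response=response, offset=offset, power=power)
        except Exception as exc:  # noqa: BLE001 - individual fits may fail
            failures.append((i, str(exc)))
            logger.warning("model %d (%s) failed: %s", i, _model_label(combo), exc)
            continue
        if power is None:
            power = model.power
        logger.info("model %d: %s aic=%.2f edf=%.2f", i, _model_label(combo),
                    model.aic, model.edf_total)
        rows.append({
            "model_id": i, "variables": combo, "label": _model_label(combo),
            "aic": model.aic, "explained_deviance": model.explained_deviance,
            "edf": model.edf_total,
        })
    if failures and not rows:
        raise SelectionError(f"every candidate fit failed; first error: {failures[0][1]}")
    if failures:
        warnings.warn(f"{len(failures)} candidate fits failed and were excluded", stacklevel=2)
    table = pd.DataFrame(rows)
    wts = akaike_weights(table["aic"], table["model_id"])
    table = table.merge(
        wts.rename(columns={"model": "model_id"})[
            ["model_id", "delta_aic", "rel_likelihood", "weight"]
        ],
        on="model_id",
    ).sort_values("aic", kind="mergesort").reset_index(drop=True)

    importance = variable_importance_from_table(table)
    best = table[table["delta_aic"] < delta_threshold]
    best_ids = best["model_id"].tolist()
    imp = dict(zip(importance["variable"], importance["importance"]))
    shared = set.intersection(*(set(v) for v in best["variables"])) if len(best) else set()

    def score(row):
        distinguishing = [c for c in row["variables"] if c not in shared]
        return sum(imp.get(candidate_column(c), 0.0) for c in distinguishing)

    ranked = sorted(
        best.to_dict("records"),
        key=lambda r: (-score(r), r["aic"], r["model_id"]),
    )
    chosen = ranked[0]
    chosen_model = fit_gam(
        covariates, [candidate_column(c) for c in chosen["variables"]],
        response=response, offset=offset, power=power,
    )
    return SelectionResult(
        table=table, importance=importance, best_ids=best_ids,
        chosen_id=int(chosen["model_id"]), chosen_model=chosen_model,
        power=float(chosen_model.power),
    )


def variable_importance_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Summed Akaike weight of the models containing each candidate."""
    acc: dict[str, float] = {}
    for _, row in table.iterrows():
        for cand in row["variables"]:
            col = candidate_column(cand)
            acc[col] = acc.get(col, 0.0) + row["weight"]
    out = pd.DataFrame(
        {"variable": list(acc.keys()), "importance": list(acc.values())}
    ).sort_values(["importance", "variable"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def variable_importance(selection: SelectionResult) -> pd.DataFrame:
    return selection.importance


def fit_seasonal_model(covariates: pd.DataFrame, candidates: list[tuple[str, int]],
                       response: str = "n_individuals", offset: str = "offset_area_km2",
                       max_size: int = 4, cor_threshold: float = 0.6,
                       power: float | None = None) -> SelectionResult:
    """Select the seasonal challenger over winter-mean and winter-sd covariates.

    The covariate table must pool the segments of every winter (no
    per-winter stratification); zero-variance columns (e.g. the sd of a
    time-constant field) are dropped with a warning before enumeration.
    """
    usable = []
    for cand in candidates:
        col = candidate_column(cand)
        if col not in covariates.columns:
            raise SelectionError(f"missing seasonal column {col}")
        if np.ptp(covariates[col].values.astype(float)) <= 0:
            warnings.warn(f"dropping constant seasonal covariate {col!r}", stacklevel=2)
            continue
        usable.append(cand)
    combos = enumerate_candidates(usable, covariates, max_size, cor_threshold)
    return select_best(covariates, combos, response=response, offset=offset, power=power)
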