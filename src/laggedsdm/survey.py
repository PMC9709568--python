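"""Segmented line-transect survey tables: I/O, condition filter, summaries.

The analysis unit is the 5 km effort segment with homogeneous detection
conditions.  A segment is retained ("good conditions") when the Beaufort
sea state is at most 3 and the observer's subjective condition is at
least medium on the ordered scale poor < medium < good < excellent;
sightings on removed segments are dropped from the analysis.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

SUBJECTIVE_ORDER = ("poor", "medium", "good", "excellent")
_SUBJ_RANK = {s: i for i, s in enumerate(SUBJECTIVE_ORDER)}


class SurveyDataError(ValueError):
    pass


def load_segments(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_sightings(path) -> pd.DataFrame:
    return pd.read_csv(path)


def good_condition_flag(segments: pd.DataFrame, max_beaufort: int = 3,
                        min_subjective: str = "medium") -> pd.Series:
    if segments[["beaufort", "subjective"]].isna().any().any():
        bad = segments.loc[segments[["beaufort", "subjective"]].isna().any(axis=1), "segment_id"]
        raise SurveyDataError(f"missing condition values on segments {list(bad)}")
    unknown = set(segments["subjective"]) - set(SUBJECTIVE_ORDER)
    if unknown:
        raise SurveyDataError(f"unknown subjective levels: {sorted(unknown)}")
    rank = segments["subjective"].map(_SUBJ_RANK)
    return (segments["beaufort"] <= max_beaufort) & (rank >= _SUBJ_RANK[min_subjective])


def filter_good_conditions(segments: pd.DataFrame, sightings: pd.DataFrame | None = None,
                           max_beaufort: int = 3, min_subjective: str = "medium"):
    """Subset segments (and optionally their sightings) to good conditions."""
    keep = good_condition_flag(segments, max_beaufort, min_subjective)
    good = segments.loc[keep].reset_index(drop=True)
    if sightings is None:
        return good
    kept = sightings[sightings["segment_id"].isin(good["segment_id"])].reset_index(drop=True)
    return good, kept


def counts_per_segment(segments: pd.DataFrame, sightings: pd.DataFrame) -> pd.Series:
    """Individuals sighted per segment (sum of group sizes; 0 if none)."""
    unknown = set(sightings["segment_id"]) - set(segments["segment_id"])
    if unknown:
        raise SurveyDataError(f"sightings reference unknown segments: {sorted(unknown)[:5]}")
    per = sightings.groupby("segment_id")["group_size"].sum()
    return per.reindex(segments["segment_id"], fill_value=0).astype(float)


def summarize_effort(segments: pd.DataFrame, sightings: pd.DataFrame,
                     grouping: str | list[str] = "day",
                     max_beaufort: int = 3, min_subjective: str = "medium") -> pd.DataFrame:
    """Effort and sighting summary per group.

    Reports, per group: total effort (km), effort in good conditions (km),
    number of individuals and number of sightings — the latter two counted
    on good-condition effort only.
    """
    if len(segments) == 0:
        cols = ["total_effort_km", "good_effort_km", "n_individuals", "n_sightings"]
        return pd.DataFrame([{c: 0.0 for c in cols}])
    unknown = set(sightings["segment_id"]) - set(segments["segment_id"])
    if unknown:
        raise SurveyDataError(f"sightings reference unknown segments: {sorted(unknown)[:5]}")
    seg = segments.copy()
    seg["good"] = good_condition_flag(seg, max_beaufort, min_subjective)
    keys = [grouping] if isinstance(grouping, str) else list(grouping)
    sgt = sightings[["segment_id", "group_size"]].merge(
        seg[["segment_id", "good"] + keys], on="segment_id", how="left"
    )
    sgt = sgt[sgt["good"]]
    eff = seg.groupby(keys).agg(
        total_effort_km=("length_km", "sum"),
        good_effort_km=("length_km", lambda s: s[seg.loc[s.index, "good"]].sum()),
    )
    obs = sgt.groupby(keys).agg(
        n_individuals=("group_size", "sum"),
        n_sightings=("group_size", "size"),
    )
    out = eff.join(obs).fillna({"n_individuals": 0, "n_sightings": 0})
    out[["n_individuals", "n_sightings"]] = out[["n_individuals", "n_sightings"]].astype(int)
    return out.reset_index()


def encounter_rate(segments: pd.DataFrame, sightings: pd.DataFrame,
                   grouping: str = "day") -> pd.Series:
    """Individuals per km of good-condition effort, per group."""
    summary = summarize_effort(segments, sightings, grouping).set_index(grouping)
    with np.errstate(invalid="ignore", divide="ignore"):
        return summary["n_individuals"] / summary["good_effort_km"]


# ---------------------------------------------------------------------------
# packaged effort/sighting summary fixture (one row per survey session)


def load_session_table() -> pd.DataFrame:
    """Per-session effort/sighting summary shipped with the package."""
    with resources.files("laggedsdm.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def summarize_sessions(table: pd.DataFrame | None = None, by: str = "winter") -> pd.DataFrame:
    """Aggregate the session-level summary to winters (or return sessions)."""
    if table is None:
        table = load_session_table()
    if by == "session":
        return table.copy()
    if by != "winter":
        raise SurveyDataError("by must be 'session' or 'winter'")
    return (
        table.groupby("winter")[
            ["total_effort_km", "good_effort_km", "n_individuals", "n_sightings"]
        ].sum().reset_index()
    )
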