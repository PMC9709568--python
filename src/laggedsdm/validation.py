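"""Simulation-based reliability assessment of predicted density maps.

A predicted density map is treated as the truth of an inhomogeneous
Poisson point process: each grid cell spawns Poisson(lambda x cell
area) individuals placed uniformly within the cell; points further than
the survey corridor (700 m) from the sampled segment are discarded, and
a point counts as detected when its distance to the track is at most
the survey ESW.  Repeating this per segment yields an ensemble of
simulated counts that is proper-scored against the observed count with
the sample (quantile) form of the continuous ranked probability score;
lower is better.  Three challengers are compared: the day-matched daily
model, a per-winter seasonal map, and a spatially uniform density.

Randomness is keyed per (segment, cell) from the master seed, so a
segment's simulated counts do not depend on iteration order, on other
segments, or on widening the corridor (extra cells only contribute
points too far away to be detected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from . import features
from .survey import counts_per_segment

DEFAULT_CORRIDOR_KM = 0.7


class ValidationError(ValueError):
    pass


def build_uniform_map(grid_like: xr.DataArray | xr.Dataset, level: float) -> xr.DataArray:
    """Constant density raster on the grid of ``grid_like`` (ind km^-2)."""
    if level < 0:
        raise ValidationError("uniform density level must be non-negative")
    ny = grid_like.sizes["y"]
    nx = grid_like.sizes["x"]
    da = xr.DataArray(
        np.full((ny, nx), float(level)),
        coords={"y": grid_like["y"].values, "x": grid_like["x"].values},
        dims=("y", "x"), name="density",
    )
    da.attrs["cell_km"] = features.cell_km_of(grid_like)
    return da


def point_segment_distance(px, py, ax, ay, bx, by):
    """Euclidean distance from points to a finite segment."""
    dx, dy = bx - ax, by - ay
    denom = dx * dx + dy * dy
    t = 0.0 if denom == 0 else np.clip(((px - ax) * dx + (py - ay) * dy) / denom, 0.0, 1.0)
    return np.hypot(px - (ax + t * dx), py - (ay + t * dy))


def _rectangular_distance(px, py, ax, ay, bx, by):
    """Perpendicular distance to the track line, flat-capped at the segment
    ends: points whose along-track projection falls outside the segment get
    an infinite distance.  This makes the detected band an exact
    2 x ESW x L rectangle and avoids double counting between consecutive
    segments of one transect.
    """
    dx, dy = bx - ax, by - ay
    length = np.hypot(dx, dy)
    if length == 0:
        return np.full(np.shape(px), np.inf)
    t = ((px - ax) * dx + (py - ay) * dy) / (length * length)
    perp = np.abs((px - ax) * dy - (py - ay) * dx) / length
    return np.where((t >= 0.0) & (t <= 1.0), perp, np.inf)


def simulate_ippp_survey(density: xr.DataArray, segments: pd.DataFrame, esw: float,
                         corridor: float = DEFAULT_CORRIDOR_KM, seed: int = 0,
                         n_iter: int = 100) -> np.ndarray:
    """Simulated detected counts, shape (n_segments, n_iter).

    ``density`` is a single (y, x) map applying to every segment passed
    (call per day for day-matched maps).  ESW must not exceed the
    corridor; a segment with an endpoint outside the map raises.
    """
    if esw > corridor:
        raise ValidationError("ESW cannot exceed the simulation corridor")
    cell = features.cell_km_of(density)
    lam = np.nan_to_num(density.values, nan=0.0)
    ny, nx = lam.shape
    lx, ly = nx * cell, ny * cell
    cell_area = cell * cell
    xc = (np.arange(nx) + 0.5) * cell
    yc = (np.arange(ny) + 0.5) * cell
    half_diag = cell * np.sqrt(2.0) / 2.0
    counts = np.zeros((len(segments), n_iter), dtype=int)
    for si, row in enumerate(segments.itertuples(index=False)):
        for ex, ey in ((row.x_start, row.y_start), (row.x_end, row.y_end)):
            if not (0 <= ex <= lx and 0 <= ey <= ly):
                raise ValidationError(f"segment {row.segment_id} lies outside the map support")
        dist_c = point_segment_distance(
            xc[None, :], yc[:, None], row.x_start, row.y_start, row.x_end, row.y_end
        )
        cand_iy, cand_ix = np.nonzero(dist_c <= corridor + half_diag)
        for iy, ix in zip(cand_iy, cand_ix):
            mu = lam[iy, ix] * cell_area
            if mu <= 0:
                continue
            rng = np.random.default_rng([seed, int(row.segment_id), int(iy * nx + ix)])
            n_pts = rng.poisson(mu, size=n_iter)
            total = int(n_pts.sum())
            if total == 0:
                continue
            px = rng.uniform(ix * cell, (ix + 1) * cell, total)
            py = rng.uniform(iy * cell, (iy + 1) * cell, total)
            d = _rectangular_distance(px, py, row.x_start, row.y_start, row.x_end, row.y_end)
            it = np.repeat(np.arange(n_iter), n_pts)
            detected = d <= min(esw, corridor)
            counts[si] += np.bincount(it[detected], minlength=n_iter)
    return counts


def crps_sample(samples, observed: float) -> float:
    """Sample-based CRPS of an ensemble against one observation.

    The empirical-distribution form mean|x_i - y| - mean|x_i - x_j| / 2,
    which the quantile decomposition evaluates identically on samples.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    m = len(x)
    if m == 0:
        raise ValidationError("empty sample set")
    term1 = np.mean(np.abs(x - observed))
    i = np.arange(1, m + 1)
    sum_abs_diff = 2.0 * np.sum((2 * i - m - 1) * x)
    return float(term1 - sum_abs_diff / (2.0 * m * m))


@dataclass
class ScoreTable:
    """Per-segment CRPS per challenger plus score-distribution summaries."""

    scores: pd.DataFrame           # segment_id, day, model, observed, crps
    simulated: dict[str, np.ndarray]  # model -> (n_segments, n_iter) counts
    n_iter: int

    def summary(self) -> pd.DataFrame:
        return (
            self.scores.groupby("model")["crps"]
            .agg(["mean", "median", "std"])
            .reset_index()
            .rename(columns={"mean": "mean_crps", "median": "median_crps", "std": "sd_crps"})
        )


def score_models(daily_maps: xr.DataArray, seasonal_map: xr.DataArray,
                 uniform_map: xr.DataArray, segments: pd.DataFrame,
                 sightings: pd.DataFrame, esw: float,
                 corridor: float = DEFAULT_CORRIDOR_KM, n_iter: int = 100,
                 seed: int = 0) -> ScoreTable:
    """Score daily / seasonal / uniform challengers on the same survey.

    The daily challenger uses the map matching each segment's sampling
    day (missing days raise); the seasonal and uniform challengers use
    one map for all segments.  Pass good-condition segments only.
    """
    observed = counts_per_segment(segments, sightings).values
    seg_order = segments.reset_index(drop=True)
    daily_days = set(daily_maps["day"].values.astype(int))
    sim: dict[str, np.ndarray] = {}
    rows = []
    for model_name, map_source in (
        ("daily", None), ("seasonal", seasonal_map), ("uniform", uniform_map),
    ):
        counts = np.zeros((len(seg_order), n_iter), dtype=int)
        for day, idx in seg_order.groupby("day").indices.items():
            if model_name == "daily":
                if int(day) not in daily_days:
                    raise ValidationError(f"no daily map for survey day {day}")
                day_map = daily_maps.sel(day=int(day))
            else:
                day_map = map_source
            counts[idx] = simulate_ippp_survey(
                day_map, seg_order.iloc[idx], esw, corridor, seed, n_iter
            )
        sim[model_name] = counts
        for si in range(len(seg_order)):
            rows.append({
                "segment_id": seg_order["segment_id"].iloc[si],
                "day": int(seg_order["day"].iloc[si]),
                "model": model_name,
                "observed": float(observed[si]),
                "crps": crps_sample(counts[si], observed[si]),
            })
    return ScoreTable(pd.DataFrame(rows), sim, n_iter)


def plot_score_densities(table: ScoreTable, path=None):
    """Kernel-density plot of the CRPS distributions per challenger."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for model, sub in table.scores.groupby("model"):
        sub["crps"].plot.kde(ax=ax, label=model)
    ax.set_xlabel("CRPS (individuals)")
    ax.set_ylabel("density")
    ax.set_xlim(left=0)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
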