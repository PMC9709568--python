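"""Covariate derivation: formulas, fronts, distances, extraction, saturation."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from laggedsdm import features
from laggedsdm.features import FeatureError


def _raster(data, cell_km=5.0, days=None):
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    days = days if days is not None else list(range(1, data.shape[0] + 1))
    ny, nx = data.shape[1:]
    da = xr.DataArray(
        data,
        coords={"day": days, "y": (np.arange(ny) + 0.5) * cell_km,
                "x": (np.arange(nx) + 0.5) * cell_km},
        dims=("day", "y", "x"),
    )
    da.attrs["cell_km"] = cell_km
    return da


class TestDerivedFields:
    def test_speed_and_eke_formulas(self):
        """U=3, V=4 everywhere -> CurrentSpeed 5 and EKE 12.5."""
        ds = xr.Dataset({"U": _raster(np.full((4, 4), 3.0)),
                         "V": _raster(np.full((4, 4), 4.0))})
        ds.attrs["cell_km"] = 5.0
        out = features.derive_dynamic_fields(ds)
        np.testing.assert_allclose(out["CurrentSpeed"].values, 5.0)
        np.testing.assert_allclose(out["EKE"].values, 12.5)

    def test_eke_is_half_speed_squared(self, small_env):
        out = features.derive_dynamic_fields(small_env)
        np.testing.assert_allclose(
            out["EKE"].values, 0.5 * out["CurrentSpeed"].values ** 2, rtol=1e-12
        )

    def test_missing_velocity_raises(self):
        ds = xr.Dataset({"U": _raster(np.zeros((4, 4)))})
        ds.attrs["cell_km"] = 5.0
        with pytest.raises(FeatureError, match="U and V"):
            features.derive_dynamic_fields(ds)

    @pytest.mark.parametrize("slope", [0.0, 2.0])
    def test_gradient_of_ramp(self, slope):
        """A linear ramp f(x) = slope * x has gradient magnitude = slope at
        interior cells; a constant field has zero gradient everywhere."""
        cell = 5.0
        x = (np.arange(8) + 0.5) * cell
        field = np.tile(slope * x, (6, 1))
        grad = features.gradient_magnitude(field, cell)
        np.testing.assert_allclose(grad[:, 1:-1], slope, atol=1e-12)


class TestFronts:
    def test_step_field_front_location(self):
        """A value jump at column k concentrates the mask on k-1..k+1."""
        field = np.zeros((6, 10))
        field[:, 5:] = 10.0
        da = _raster(field)
        fm = features.detect_fronts(da, 0.90)
        mask = fm.mask.isel(day=0).values
        cols = np.unique(np.nonzero(mask)[1])
        assert set(cols) <= {4, 5}
        assert mask.any()
        # brute-force: flagged cells are exactly the positive-gradient cells
        # at or above the quantile
        grad = features.gradient_magnitude(field, 5.0)
        thr = np.quantile(grad, 0.90)
        np.testing.assert_array_equal(mask, (grad >= thr) & (grad > 0))

    def test_constant_field_empty_mask(self):
        da = _raster(np.full((5, 5), 3.3))
        with pytest.warns(UserWarning, match="constant field"):
            fm = features.detect_fronts(da, 0.90)
        assert not fm.mask.values.any()
        assert fm.degenerate_days == [1]

    def test_zero_quantile_flags_all_nonzero_gradient(self):
        field = np.zeros((6, 10))
        field[:, 5:] = 1.0
        fm = features.detect_fronts(_raster(field), 0.0)
        grad = features.gradient_magnitude(field, 5.0)
        np.testing.assert_array_equal(fm.mask.isel(day=0).values, grad > 0)

    def test_distance_to_front_geometry(self):
        """Front on column 3, cell 5 km: column 6 sits 15 km away; the front
        itself is at distance zero and everything else strictly positive."""
        field = np.zeros((4, 8))
        mask = np.zeros((1, 4, 8), dtype=bool)
        mask[0, :, 3] = True
        fm = features.FrontMask(_raster(field).copy(data=mask).astype(bool), "f", 0.9,
                                np.array([1.0]))
        dist = features.distance_to_front(fm)
        got = dist.isel(day=0).values
        assert got[2, 6] == pytest.approx(15.0)
        np.testing.assert_allclose(got[:, 3], 0.0)
        assert (got[:, [0, 1, 2, 4, 5, 6, 7]] > 0).all()

    def test_distance_matches_bruteforce(self, rng):
        """Random sparse masks: EDT distance equals the exhaustive
        nearest-front-cell search."""
        cell = 5.0
        mask = rng.random((1, 7, 9)) < 0.15
        mask[0, 0, 0] = True  # ensure non-empty
        fm = features.FrontMask(
            _raster(np.zeros((7, 9)), cell).copy(data=mask).astype(bool), "f", 0.9,
            np.array([1.0]))
        dist = features.distance_to_front(fm).isel(day=0).values
        fy, fx = np.nonzero(mask[0])
        for iy in range(7):
            for ix in range(9):
                d = np.min(np.hypot((fy - iy) * cell, (fx - ix) * cell))
                assert dist[iy, ix] == pytest.approx(d)

    def test_empty_mask_distance_is_missing(self):
        mask = np.zeros((1, 4, 4), dtype=bool)
        fm = features.FrontMask(_raster(np.zeros((4, 4))).copy(data=mask).astype(bool),
                                "f", 0.9, np.array([np.nan]))
        with pytest.warns(UserWarning, match="empty front mask"):
            dist = features.distance_to_front(fm)
        assert np.isnan(dist.values).all()

    def test_persistence_counts(self):
        """Alternating on/off over 30 days -> 15; always -> 30; never -> 0."""
        mask = np.zeros((30, 3, 3), dtype=bool)
        mask[::2, 0, 0] = True
        mask[:, 1, 1] = True
        fm = features.FrontMask(
            _raster(np.zeros((30, 3, 3))).copy(data=mask).astype(bool), "f", 0.9,
            np.ones(30))
        pers = features.front_persistence(fm).values
        assert pers[0, 0] == 15
        assert pers[1, 1] == 30
        assert pers[2, 2] == 0
        # total persistence equals the summed daily mask counts
        assert pers.sum() == mask.sum()


class TestSeasonalSummaries:
    def test_two_day_mean_and_sd(self):
        data = np.stack([np.full((3, 3), 1.0), np.full((3, 3), 5.0)])
        ds = xr.Dataset({"Temp": _raster(data)})
        ds.attrs["cell_km"] = 5.0
        out = features.seasonal_summaries(ds)
        np.testing.assert_allclose(out["mean_Temp"].values, 3.0)
        # sd with denominator n-1: sqrt(((1-3)^2 + (5-3)^2) / 1)
        np.testing.assert_allclose(out["sd_Temp"].values, np.sqrt(8.0))

    def test_constant_in_time_field(self):
        data = np.tile(np.arange(9.0).reshape(3, 3), (5, 1, 1))
        ds = xr.Dataset({"Temp": _raster(data)})
        ds.attrs["cell_km"] = 5.0
        out = features.seasonal_summaries(ds)
        np.testing.assert_allclose(out["sd_Temp"].values, 0.0)
        np.testing.assert_allclose(out["mean_Temp"].values, data[0])

    def test_single_day_raises(self):
        ds = xr.Dataset({"Temp": _raster(np.zeros((1, 3, 3)))})
        ds.attrs["cell_km"] = 5.0
        with pytest.raises(FeatureError, match="fewer than 2"):
            features.seasonal_summaries(ds)


class TestExtraction:
    def test_lag_indexing_contract(self, small_env):
        """Lag 0 reads the sampling day; lag 10 on day 40 reads day 30."""
        seg = pd.DataFrame({
            "segment_id": [0], "day": [40],
            "x_start": [20.0], "y_start": [30.0], "x_end": [25.0], "y_end": [30.0],
            "length_km": [5.0],
        })
        table = features.extract_at_segments(small_env, seg, [0, 10], ["Temp"])
        ix, iy = features.cell_index(small_env, 22.5, 30.0)
        assert table["Temp_lag0"].iloc[0] == small_env["Temp"].sel(day=40).values[iy, ix]
        assert table["Temp_lag10"].iloc[0] == small_env["Temp"].sel(day=30).values[iy, ix]

    def test_random_triples_match_direct_lookup(self, small_scene, rng):
        """100 random (segment, variable, lag) triples equal direct lookups."""
        env, segments = small_scene["env"], small_scene["segments"]
        lags = (0, 1, 2, 4, 7, 10, 30)
        variables = ["Temp", "Chl", "MLD", "EKE"]
        table = features.extract_at_segments(env, segments, lags, variables)
        for _ in range(100):
            row = int(rng.integers(len(segments)))
            var = variables[int(rng.integers(len(variables)))]
            lag = lags[int(rng.integers(len(lags)))]
            seg = segments.iloc[row]
            cx = (seg.x_start + seg.x_end) / 2
            cy = (seg.y_start + seg.y_end) / 2
            ix, iy = features.cell_index(env, cx, cy)
            want = env[var].sel(day=int(seg.day) - lag).values[iy, ix]
            assert table[f"{var}_lag{lag}"].iloc[row] == want

    def test_lag_before_series_start_raises(self, small_env):
        seg = pd.DataFrame({
            "segment_id": ["s9"], "day": [20],
            "x_start": [10.0], "y_start": [10.0], "x_end": [15.0], "y_end": [10.0],
            "length_km": [5.0],
        })
        with pytest.raises(FeatureError, match="s9"):
            features.extract_at_segments(small_env, seg, [30], ["Temp"])


class TestSaturation:
    def test_normal_sample_clipped_at_quantiles(self, rng):
        x = rng.standard_normal(1000)
        out = features.saturate_quantiles(x, 0.01, 0.99)
        # declared convention: inner order statistics at each tail
        lo = np.quantile(x, 0.01, method="higher")
        hi = np.quantile(x, 0.99, method="lower")
        assert out.min() == lo and out.max() == hi
        # and they sit within interpolation distance of the type-7 values
        assert lo == pytest.approx(np.quantile(x, 0.01), abs=5e-3)
        assert hi == pytest.approx(np.quantile(x, 0.99), abs=5e-3)

    def test_interior_values_unchanged(self):
        x = np.linspace(0.4, 0.6, 50)
        base = np.concatenate([[0.0, 1.0], x])
        out = features.saturate_quantiles(base, 0.01, 0.99)
        np.testing.assert_array_equal(out[2:], x)

    def test_constant_vector_unchanged(self):
        x = np.full(20, 7.0)
        np.testing.assert_array_equal(features.saturate_quantiles(x), x)

    def test_empty_input_raises(self):
        with pytest.raises(FeatureError):
            features.saturate_quantiles([])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=80),
           st.floats(0.0, 0.3), st.floats(0.7, 1.0))
    def test_idempotent_and_order_preserving(self, values, lo, hi):
        """Clipping twice equals clipping once, and order never flips."""
        x = np.array(values)
        once = features.saturate_quantiles(x, lo, hi)
        twice = features.saturate_quantiles(once, lo, hi)
        np.testing.assert_allclose(once, twice, rtol=0, atol=1e-9)
        order = np.argsort(x, kind="stable")
        assert (np.diff(once[order]) >= -1e-12).all()
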