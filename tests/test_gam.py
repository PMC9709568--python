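"""Penalized Tweedie count-regression core.

The Tweedie series log-density is checked against reference values
computed once with an independent R implementation (mgcv::ldTweedie),
and unpenalized fits are cross-checked against statsmodels GLM with the
same variance function — two independent routes to the same numbers.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laggedsdm import gam
from laggedsdm.gam import (
    FittedHabitatModel,
    GamError,
    akaike_weights,
    fit_gam,
    rmse,
    tweedie_deviance,
    tweedie_loglik,
)

# log-densities from mgcv::ldTweedie for y = (0, 0, 1, 3, 7.5, 12),
# mu = (0.5, 2, 1.5, 2.5, 6, 4), frozen as an independent oracle
_Y = np.array([0.0, 0.0, 1.0, 3.0, 7.5, 12.0])
_MU = np.array([0.5, 2.0, 1.5, 2.5, 6.0, 4.0])
_REFERENCE = {
    (1.2, 1.3): [-0.5522588245, -1.6741356986, -1.2002293117,
                 -1.7890975343, -2.3747883374, -5.3522879556],
    (1.5, 1.3): [-1.0878565864, -2.1757131729, -1.2656951524,
                 -1.9747250745, -2.6612716586, -4.5997067619],
    (1.8, 1.3): [-3.3482713973, -4.4180705961, -1.2345359123,
                 -2.1556537175, -2.9763806574, -4.3403148423],
    (1.5, 0.7): [-2.0203050891, -4.0406101782, -0.9309942066,
                 -1.6457131067, -2.3740574515, -5.6860030192],
}


class TestTweedieDensity:
    @pytest.mark.parametrize("p,phi", sorted(_REFERENCE))
    def test_series_matches_reference(self, p, phi):
        got = tweedie_loglik(_Y, _MU, phi, p)
        np.testing.assert_allclose(got, _REFERENCE[(p, phi)], atol=1e-8)

    def test_zero_mass_closed_form(self):
        p, phi, mu = 1.4, 0.9, 2.3
        got = tweedie_loglik(np.array([0.0]), np.array([mu]), phi, p)
        assert got[0] == pytest.approx(-mu ** (2 - p) / (phi * (2 - p)))

    def test_density_integrates_to_one(self):
        """Point mass at zero plus quadrature over y > 0 sums to ~1."""
        from scipy import integrate

        p, phi, mu = 1.5, 1.0, 2.0
        mass0 = np.exp(tweedie_loglik(np.array([0.0]), np.array([mu]), phi, p))[0]
        pos, _ = integrate.quad(
            lambda y: np.exp(tweedie_loglik(np.array([y]), np.array([mu]), phi, p))[0],
            1e-9, 60.0, limit=300,
        )
        assert mass0 + pos == pytest.approx(1.0, abs=1e-6)

    def test_deviance_zero_at_saturation(self):
        y = np.array([0.5, 2.0, 7.0])
        np.testing.assert_allclose(tweedie_deviance(y, y, 1.5), 0.0, atol=1e-12)
        assert (tweedie_deviance(y, y * 2, 1.5) > 0).all()

    def test_invalid_power_rejected(self):
        with pytest.raises(GamError):
            tweedie_loglik(_Y, _MU, 1.0, 2.0)


def _count_frame(rng, n=800, fn=np.sin):
    x = rng.uniform(0, 6, n)
    area = rng.uniform(0.5, 2.0, n)
    y = rng.poisson(area * np.exp(0.5 + fn(x))).astype(float)
    return pd.DataFrame({"x": x, "n_individuals": y, "offset_area_km2": area})


class TestFitGam:
    def test_unpenalized_fit_matches_statsmodels(self, rng):
        """With the penalty off, coefficients agree with statsmodels GLM
        under the same Tweedie variance function and offset."""
        import statsmodels.api as sm
        from statsmodels.genmod.families import Tweedie
        from statsmodels.genmod.families.links import Log

        df = _count_frame(rng)
        mine = fit_gam(df, ["x"], power=1.3, alpha=1e-9)
        X = mine.design(df)
        ref = sm.GLM(df["n_individuals"], X, family=Tweedie(var_power=1.3, link=Log()),
                     offset=np.log(df["offset_area_km2"])).fit()
        np.testing.assert_allclose(mine.coef, ref.params, atol=1e-5)

    def test_null_signal_shrinks_smooths(self, rng):
        """Constant-mean counts: each smooth is penalized down to edf <= 1.1."""
        df = _count_frame(rng, fn=lambda x: 0.0 * x)
        model = fit_gam(df, ["x"], power=1.3)
        assert model.edf_by_term["x"] <= 1.1

    def test_recovers_sine_signal(self, rng):
        """Counts from log-lambda = 0.5 + sin(x), n = 2000: fitted smooth
        correlates > 0.95 with the truth over the observed range."""
        df = _count_frame(rng, n=2000)
        model = fit_gam(df, ["x"], power=1.3)
        grid = pd.DataFrame({"x": np.linspace(0.05, 5.95, 150)})
        fitted = np.log(model.predict(grid))
        truth = 0.5 + np.sin(grid["x"].values)
        assert np.corrcoef(fitted, truth)[0, 1] > 0.95

    def test_offset_equivariance(self, rng):
        """Doubling every offset lowers the intercept by log 2 and leaves
        the smooth coefficients unchanged."""
        df = _count_frame(rng)
        df2 = df.assign(offset_area_km2=2 * df["offset_area_km2"])
        m1 = fit_gam(df, ["x"], power=1.3, alpha=1.0)
        m2 = fit_gam(df2, ["x"], power=1.3, alpha=1.0)
        assert m1.intercept - m2.intercept == pytest.approx(np.log(2), abs=1e-8)
        np.testing.assert_allclose(m1.coef[1:], m2.coef[1:], atol=1e-6)

    def test_fit_invariant_to_column_order(self, rng):
        df = _count_frame(rng)
        df["z"] = rng.uniform(0, 1, len(df))
        m1 = fit_gam(df, ["x", "z"], power=1.3, alpha=1.0)
        m2 = fit_gam(df[list(df.columns[::-1])], ["x", "z"], power=1.3, alpha=1.0)
        assert m1.aic == pytest.approx(m2.aic, abs=1e-9)
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-10)

    def test_constant_covariate_dropped_with_warning(self, rng):
        df = _count_frame(rng)
        df["flat"] = 3.0
        with pytest.warns(UserWarning, match="flat"):
            model = fit_gam(df, ["x", "flat"], power=1.3, alpha=1.0)
        assert model.term_names() == ["x"]

    def test_duplicated_covariate_raises(self, rng):
        df = _count_frame(rng)
        df["x2"] = df["x"]
        with pytest.raises(GamError, match="collinear|converge"):
            fit_gam(df, ["x", "x2"], power=1.3, alpha=0.0)

    def test_explained_deviance_monotone_in_nesting(self, rng):
        """At fixed smoothing, adding a term never lowers explained deviance."""
        df = _count_frame(rng)
        df["z"] = rng.uniform(0, 1, len(df))
        m1 = fit_gam(df, ["x"], power=1.3, alpha=1.0)
        m2 = fit_gam(df, ["x", "z"], power=1.3, alpha=1.0)
        assert m2.explained_deviance >= m1.explained_deviance - 1e-9

    def test_power_profiling_picks_low_power_for_poisson(self, rng):
        df = _count_frame(rng)
        model = fit_gam(df, ["x"])  # power profiled
        assert 1.0 < model.power <= 1.3


class TestPrediction:
    def test_intercept_only_prediction(self, rng):
        df = _count_frame(rng, fn=lambda x: 0.0 * x)
        model = fit_gam(df, [], power=1.3)
        mu, se = model.predict(df, se=True)
        np.testing.assert_allclose(mu, np.exp(model.intercept))
        assert (se > 0).all() and np.ptp(se) < 1e-12

    def test_prediction_consistent_with_fitted(self, rng):
        df = _count_frame(rng)
        model = fit_gam(df, ["x"], power=1.3)
        mu = model.predict(df, offset=np.log(df["offset_area_km2"].values))
        np.testing.assert_allclose(mu, model.fitted, rtol=1e-10)

    def test_missing_column_raises(self, rng):
        df = _count_frame(rng)
        model = fit_gam(df, ["x"], power=1.3)
        with pytest.raises(GamError, match="missing covariate"):
            model.predict(pd.DataFrame({"y": [1.0]}))

    def test_json_roundtrip_preserves_predictions(self, rng):
        df = _count_frame(rng)
        model = fit_gam(df, ["x"], power=1.3)
        clone = FittedHabitatModel.from_json(model.to_json())
        grid = pd.DataFrame({"x": np.linspace(0, 6, 50)})
        np.testing.assert_allclose(model.predict(grid), clone.predict(grid), rtol=1e-12)
        mu1, se1 = model.predict(grid, se=True)
        mu2, se2 = clone.predict(grid, se=True)
        np.testing.assert_allclose(se1, se2, rtol=1e-9)
        assert clone.aic == model.aic


class TestModelComparison:
    def test_weights_examples(self):
        out = akaike_weights([100.0, 102.0])
        np.testing.assert_allclose(out["weight"].values, [0.731, 0.269], atol=1e-3)
        np.testing.assert_allclose(akaike_weights([5.0])["weight"].values, [1.0])
        np.testing.assert_allclose(akaike_weights([7.0] * 4)["weight"].values, 0.25)

    def test_delta_of_best_is_zero(self):
        out = akaike_weights([12.0, 10.0, 30.0])
        assert out["delta_aic"].iloc[0] == 0.0
        assert out["model"].iloc[0] == 1

    def test_nonfinite_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            out = akaike_weights([10.0, np.inf, 12.0])
        assert len(out) == 2
        assert out["weight"].sum() == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e4), min_size=1, max_size=12))
    def test_weights_sum_to_one_and_antimonotone(self, aics):
        """Weights always sum to 1 and never increase with AIC."""
        out = akaike_weights(aics)
        assert out["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(out["weight"].values) <= 1e-12).all()

    def test_rmse(self, rng):
        df = _count_frame(rng)
        model = fit_gam(df, ["x"], power=1.3)
        by_hand = np.sqrt(np.mean((model.response - model.fitted) ** 2))
        assert rmse(model) == pytest.approx(by_hand)
        perfect = FittedHabitatModel.from_json(model.to_json())
        perfect.fitted = perfect.response.copy()
        assert rmse(perfect) == 0.0
        perfect.fitted = perfect.response + np.resize([1.0, -1.0], len(perfect.response))
        assert rmse(perfect) == pytest.approx(1.0)
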