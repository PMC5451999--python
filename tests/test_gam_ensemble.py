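import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pm25ens import (bagging_fit, ensemble_predict, ensemble_weights,
                     expected_unique_fraction, fit_additive, oob_predict,
                     term_variance_report)
from pm25ens.gam_ensemble import (EnsembleModel, EnsemblePrediction, FitError,
                                  _weighted_sd, lin, s, te)


def _smooth_frame(n=600, noise_sd=0.1, seed=1):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-3, 3, n)
    truth = np.sin(x) + 0.3 * x
    y = truth + noise_sd * rng.standard_normal(n)
    return pd.DataFrame({"y": y, "x": x}), truth


class TestFitAdditive:
    def test_planted_smooth_recovered(self):
        n, noise_sd = 600, 0.1
        df, truth = _smooth_frame(n, noise_sd)
        fit = fit_additive(df, "y", [s("x", 8)])
        interior = (df["x"] > -2.5) & (df["x"] < 2.5)
        rmse = float(np.sqrt(np.mean(
            (fit.predict(df[interior]) - truth[interior]) ** 2)))
        assert rmse < 3 * noise_sd / np.sqrt(n) * np.sqrt(fit.edf)

    def test_nests_linear_fit(self, rng):
        n = 300
        x = rng.uniform(0, 1, n)
        df = pd.DataFrame({"y": 2 * x + 0.05 * rng.standard_normal(n), "x": x})
        r2_lin = fit_additive(df, "y", [lin("x")]).r2
        r2_smooth = fit_additive(df, "y", [s("x")]).r2
        assert r2_smooth >= r2_lin - 1e-9

    def test_constant_response(self, rng):
        df = pd.DataFrame({"y": np.ones(100), "x": rng.standard_normal(100)})
        fit = fit_additive(df, "y", [s("x")])
        assert fit.r2 == 0.0
        np.testing.assert_allclose(fit.predict(df), 1.0, atol=1e-8)

    def test_df_capped_at_ten(self, rng):
        df = pd.DataFrame({"y": rng.standard_normal(200),
                           "x": rng.standard_normal(200)})
        fit = fit_additive(df, "y", [s("x", 25)])
        assert fit.terms[0].df == 10

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"y": rng.standard_normal(100), "a": x, "b": x})
        with pytest.raises(FitError):
            fit_additive(df, "y", [lin("a"), lin("b")])

    def test_missing_covariate_named(self, rng):
        df = pd.DataFrame({"y": rng.standard_normal(50),
                           "x": rng.standard_normal(50)})
        fit = fit_additive(df, "y", [s("x")])
        with pytest.raises(KeyError, match="x"):
            fit.predict(df.rename(columns={"x": "z"}))

    def test_extrapolation_flagged(self):
        df, _ = _smooth_frame()
        fit = fit_additive(df, "y", [s("x")])
        _, flags = fit.predict(pd.DataFrame({"x": [0.0, 99.0]}),
                               return_flags=True)
        assert list(flags) == [False, True]

    def test_bivariate_wind_surface(self, rng):
        n = 800
        e, no = rng.normal(0, 2, n), rng.normal(0, 2, n)
        y = -0.3 * np.sqrt(e ** 2 + no ** 2) + 0.05 * rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "e": e, "n": no})
        fit = fit_additive(df, "y", [te("e", "n")])
        assert fit.r2 > 0.8

    def test_variance_report_ranks_terms(self):
        df, _ = _smooth_frame()
        rng = np.random.default_rng(0)
        df["junk"] = rng.standard_normal(len(df))
        rep = term_variance_report(df, "y", [s("x"), s("junk")])
        rep = rep.set_index("term")
        assert rep.loc["s(x)", "univariate_r2"] > rep.loc["s(junk)", "univariate_r2"]
        assert rep.loc["s(x)", "multivariate_delta_r2"] > 0.5


class TestBootstrapGeometry:
    def test_closed_form_unique_fraction(self):
        # 1 − (1 − 1/n)^n at the study's sample size ⇒ the 63.2/36.8 split
        assert expected_unique_fraction(35040) * 100 == pytest.approx(63.2, abs=0.05)

    def test_simulated_unique_fraction(self, rng):
        n = 35040
        fracs = [np.unique(rng.integers(0, n, n)).size / n for _ in range(200)]
        assert np.mean(fracs) * 100 == pytest.approx(63.2, abs=0.1)


class TestEnsembleWeights:
    def test_hand_example(self):
        np.testing.assert_allclose(ensemble_weights([0.5, 1.0]), [0.2, 0.8])

    def test_equal_scores_give_uniform(self):
        np.testing.assert_allclose(ensemble_weights([0.7] * 4), [0.25] * 4)

    def test_all_zero_warns_uniform(self):
        with pytest.warns(UserWarning):
            w = ensemble_weights([0.0, 0.0])
        np.testing.assert_allclose(w, [0.5, 0.5])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_weights_sum_to_one(self, r2s):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = ensemble_weights(r2s)
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()


class TestEnsembleSd:
    def test_agreeing_members_have_zero_sd(self):
        preds = np.full((5, 3), 2.0)
        w = np.full(5, 0.2)
        mean = w @ preds
        np.testing.assert_allclose(mean, 2.0)
        np.testing.assert_allclose(_weighted_sd(preds, w, mean), 0.0)

    def test_two_member_hand_value(self):
        preds = np.array([[1.0], [3.0]])
        w = np.array([0.5, 0.5])
        mean = w @ preds
        assert mean[0] == pytest.approx(2.0)
        assert _weighted_sd(preds, w, mean)[0] == pytest.approx(np.sqrt(2.0))

    def test_zero_weight_member_ignored(self):
        preds = np.array([[5.0], [99.0]])
        w = np.array([1.0, 0.0])
        mean = w @ preds
        assert mean[0] == 5.0
        assert _weighted_sd(preds, w, mean)[0] == 0.0      # M = 1

    def test_equal_weights_reduce_to_sample_sd(self, rng):
        preds = rng.standard_normal((30, 7))
        w = np.full(30, 1.0 / 30)
        mean = w @ preds
        np.testing.assert_allclose(_weighted_sd(preds, w, mean),
                                   preds.std(axis=0, ddof=1), rtol=1e-10)


class TestBagging:
    @staticmethod
    def _frame(n=300, seed=9):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-2, 2, n)
        z = rng.uniform(-2, 2, n)
        y = np.sin(2 * x) + 0.5 * z + 0.15 * rng.standard_normal(n)
        return pd.DataFrame({"y": y, "x": x, "z": z})

    def test_single_member_equals_single_model(self):
        df = self._frame()
        model = bagging_fit(df, "y", [s("x"), lin("z")], B=1, seed=4)
        pred = ensemble_predict(model, df)
        np.testing.assert_allclose(pred.mean, model.members[0].predict(df))
        np.testing.assert_allclose(pred.sd, 0.0)

    def test_same_seed_bit_identical(self):
        df = self._frame()
        terms = [s("x"), lin("z")]
        m1 = bagging_fit(df, "y", terms, B=8, seed=7)
        m2 = bagging_fit(df, "y", terms, B=8, seed=7)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(ensemble_predict(m1, df).mean,
                                      ensemble_predict(m2, df).mean)

    def test_weighted_mean_bounded_by_members(self):
        df = self._frame()
        model = bagging_fit(df, "y", [s("x"), lin("z")], B=10, seed=3)
        preds = np.vstack([m.predict(df) for m in model.members])
        mean = ensemble_predict(model, df).mean
        assert (mean <= preds.max(axis=0) + 1e-12).all()
        assert (mean >= preds.min(axis=0) - 1e-12).all()

    def test_oob_indices_disjoint_from_bag(self):
        df = self._frame()
        model = bagging_fit(df, "y", [s("x"), lin("z")], B=5, seed=2)
        rng = np.random.default_rng(2)
        n = len(df)
        for m in model.members:
            idx = rng.integers(0, n, n)
            assert np.intersect1d(np.unique(idx), m.oob_index).size == 0

    def test_oob_predict_close_to_truth_but_honest(self):
        df = self._frame(n=500)
        model = bagging_fit(df, "y", [s("x"), lin("z")], B=20, seed=5)
        mu = oob_predict(model, df)
        r2 = 1 - np.sum((df["y"] - mu) ** 2) / np.sum((df["y"] - df["y"].mean()) ** 2)
        assert 0.7 < r2 <= 1.0
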