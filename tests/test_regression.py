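"""Cp selection, OLS coefficients, the smearing estimator, and validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from conftest import oracle_best_subset_by_cp
from nutlim.regression import (
    BestSubsetsSmearingRegressor, RegressionModel, best_subsets, expand_design,
    fit_ols, log_transform_check, mallows_cp, predict_concentration,
    smearing_factor, validate_holdout,
)
from nutlim.synthetic_data import gen_catchment_table, gen_observed_medians


def _design(n=200, k=5, n_active=2, sigma=0.3, seed=0, beta=1.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, k)),
                     columns=[f"x_{j+1}" for j in range(k)])
    coefs = np.zeros(k)
    coefs[:n_active] = [beta * (1 if j % 2 == 0 else -1) for j in range(n_active)]
    y = 0.5 + X.to_numpy() @ coefs + rng.normal(0, sigma, n)
    return X, y, coefs


class TestLogTransformCheck:
    def test_lognormal_medians_improve_normality(self):
        rng = np.random.default_rng(2)
        better = 0
        for s in range(10):
            med = np.exp(rng.normal(-0.5, 0.8, 120))
            rep = log_transform_check(med)
            better += rep["p_log"] > rep["p_raw"]
        assert better >= 9

    def test_degenerate_response_flagged_not_raised(self):
        rep = log_transform_check([2.0, 2.0, 2.0])
        assert np.isnan(rep["p_log"])

    def test_zero_median_is_error(self):
        with pytest.raises(ValueError, match="non-positive"):
            log_transform_check([0.5, 0.0, 0.7])


class TestMallowsCp:
    def test_plug_in_arithmetic(self):
        assert mallows_cp(sse_p=30, p=3, sigma2_full=2, n=20) == pytest.approx(1.0)

    def test_full_model_identity(self):
        X, y, _ = _design(seed=4)
        res = best_subsets(X, y)
        full = res.candidates.loc[res.candidates["p"] == res.candidates["p"].max()]
        assert full["cp"].iloc[0] == pytest.approx(full["p"].iloc[0], abs=1e-6)

    def test_nonpositive_variance_is_error(self):
        with pytest.raises(ValueError):
            mallows_cp(10, 2, 0.0, 20)

    def test_noise_predictor_raises_cp_by_about_two(self):
        # adding a pure-noise column costs ~2 - (dSSE/sigma2) in Cp
        X, y, _ = _design(n=300, k=3, n_active=2, seed=9)
        res = best_subsets(X, y)
        c = res.candidates.set_index("subset")
        base = c.loc[[("x_1", "x_2")]].iloc[0]
        withnoise = c.loc[[("x_1", "x_2", "x_3")]].iloc[0]
        expected_rise = 2 - (base["sse"] - withnoise["sse"]) / res.sigma2_full
        assert withnoise["cp"] - base["cp"] == pytest.approx(expected_rise, abs=1e-9)


class TestBestSubsets:
    def test_single_strong_predictor_selected(self):
        X, y, _ = _design(k=1, n_active=1, seed=1)
        assert best_subsets(X, y).chosen == ("x_1",)

    def test_active_pair_recovered(self):
        X, y, _ = _design(n=200, k=5, n_active=2, sigma=0.3, seed=12)
        chosen = best_subsets(X, y).chosen
        assert {"x_1", "x_2"} <= set(chosen)

    def test_all_noise_favours_intercept_only(self):
        # each of 5 noise blocks enters with prob ~ P(chi2_1 > 2) ~ 0.16, so
        # over seeds the intercept-only model is modal and the mean selected
        # size stays below ~1.5
        sizes, empties = [], 0
        for seed in range(30):
            X, y, _ = _design(n=200, k=5, n_active=0, seed=seed)
            chosen = best_subsets(X, y).chosen
            sizes.append(len(chosen))
            empties += chosen == ()
        assert np.mean(sizes) <= 1.5
        assert empties >= 8

    def test_matches_bruteforce_oracle(self):
        for seed in range(5):
            X, y, _ = _design(n=60, k=6, n_active=2, sigma=0.5, seed=seed)
            chosen = best_subsets(X, y).chosen
            oracle_cols, _ = oracle_best_subset_by_cp(X.to_numpy(), y)
            assert chosen == tuple(X.columns[list(oracle_cols)])

    def test_categorical_block_enters_together(self):
        rng = np.random.default_rng(6)
        n = 300
        biome = rng.choice(["a", "b", "c"], n)
        effect = pd.Series(biome).map({"a": 0.0, "b": 1.0, "c": -1.0}).to_numpy()
        X = pd.DataFrame({"x_1": rng.standard_normal(n), "c_biome": biome})
        y = effect + rng.normal(0, 0.3, n)
        res = best_subsets(X, y)
        assert "c_biome" in res.chosen
        members = res.blocks["c_biome"]
        assert len(members) == 2  # 3 levels minus the reference

    def test_collinear_design_is_error(self):
        X, y, _ = _design(n=50, k=2, seed=0)
        X["x_dup"] = X["x_1"]
        with pytest.raises(ValueError, match="collinear|rank"):
            best_subsets(X, y)

    def test_prescreen_pool_capped(self):
        X, y, _ = _design(n=150, k=8, n_active=2, seed=3)
        res = best_subsets(X, y, max_exhaustive=4)
        assert len(res.screened_pool) == 4
        assert {"x_1", "x_2"} <= set(res.screened_pool)


class TestFitAndSmearing:
    def test_perfect_fit_gives_unit_smearing(self):
        X = pd.DataFrame({"x_1": np.arange(10, dtype=float)})
        y = 0.3 + 2.0 * X["x_1"].to_numpy()
        m = fit_ols(X, y)
        assert m.smearing == pytest.approx(1.0, abs=1e-10)
        assert m.r2 == pytest.approx(1.0)
        assert np.allclose(m.residuals, 0, atol=1e-10)

    def test_closed_form_smearing_value(self):
        assert smearing_factor([np.log(2), -np.log(2)]) == pytest.approx(1.25)

    def test_residuals_sum_to_zero_and_s_at_least_one(self):
        X, y, _ = _design(seed=21)
        m = fit_ols(X, y, subset=("x_1", "x_2"))
        assert abs(m.residuals.sum()) < 1e-8
        assert m.smearing >= 1.0

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.standard_normal((10, 3)), columns=["x_1", "x_2", "x_3"])
        y = rng.standard_normal(10)
        m = fit_ols(X, y)
        D = np.column_stack([np.ones(10), X.to_numpy()])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert m.intercept == pytest.approx(beta[0], rel=1e-9)
        np.testing.assert_allclose(list(m.beta.values()), beta[1:], rtol=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-3, max_value=3, allow_nan=False),
                    min_size=2, max_size=40))
    def test_smearing_at_least_one_for_centred_residuals(self, resid):
        r = np.asarray(resid) - np.mean(resid)
        assert smearing_factor(r) >= 1.0 - 1e-12  # Jensen: mean(e^r) >= e^mean(r)


class TestPrediction:
    def test_closed_form_with_smearing(self):
        m = RegressionModel(
            analyte="TN", selected_predictors=("x_1",), blocks={"x_1": ["x_1"]},
            beta={"x_1": 1.0}, intercept=0.5, residuals=np.zeros(3),
            sigma2_hat=0.0, r2=1.0, smearing=1.25, n=3, p=2,
            coef_se={"x_1": 0.0}, coef_p={"x_1": 0.0})
        X = pd.DataFrame({"x_1": [-0.5]})  # linear predictor = 0
        assert predict_concentration(m, X)[0] == pytest.approx(1.25)
        m.smearing = 1.0
        assert predict_concentration(m, X)[0] == pytest.approx(1.0)

    def test_missing_predictor_raises_keyerror(self):
        X, y, _ = _design(seed=5)
        m = fit_ols(X, y, subset=("x_1",))
        with pytest.raises(KeyError, match="x_1"):
            predict_concentration(m, pd.DataFrame({"x_9": [1.0]}))

    def test_training_mean_prediction_at_least_geometric_mean(self):
        X, y, _ = _design(n=100, seed=31)
        m = fit_ols(X, y, subset=("x_1", "x_2"))
        pred = predict_concentration(m, X)
        fitted_gmean = np.exp(np.mean(np.log(pred / m.smearing)))
        assert pred.mean() >= fitted_gmean


class TestHoldoutValidation:
    def test_training_set_reproduces_training_r2(self):
        X, y, _ = _design(n=150, seed=41)
        m = fit_ols(X, y, subset=("x_1", "x_2"))
        rep = validate_holdout(m, X, np.exp(y))
        assert rep["r2"] == pytest.approx(m.r2, abs=1e-9)

    def test_doubled_predictions_give_plus_hundred_bias(self):
        X = pd.DataFrame({"x_1": np.linspace(-1, 1, 20)})
        y = 0.2 + 0.7 * X["x_1"].to_numpy()  # exact fit, S = 1
        m = fit_ols(X, y)
        exact = validate_holdout(m, X, np.exp(y))
        assert exact["bias_percent"] == pytest.approx(0.0, abs=1e-8)
        m.smearing *= 2
        assert validate_holdout(m, X, np.exp(y))["bias_percent"] == pytest.approx(100.0)

    def test_small_holdout_is_error(self):
        X, y, _ = _design(seed=2)
        m = fit_ols(X, y, subset=("x_1",))
        with pytest.raises(ValueError, match="at least 3"):
            validate_holdout(m, X.head(2), np.exp(y[:2]))

    def test_bias_small_on_held_out_synthetic_truth(self):
        biases = []
        for seed in range(20):
            X, y, _ = _design(n=250, sigma=0.3, seed=seed + 100)
            m = fit_ols(X.head(200), y[:200], subset=("x_1", "x_2"))
            rep = validate_holdout(m, X.tail(50), np.exp(y[200:]))
            biases.append(rep["bias_percent"])
        assert abs(np.mean(biases)) < 5.0


class TestEstimator:
    def test_fit_predict_and_attributes(self):
        catch, truth = gen_catchment_table(n_catchments=300, seed=5)
        med = gen_observed_medians(truth, seed=6)
        tn = med.loc[med["analyte"] == "TN"]
        X = catch[[c for c in catch.columns if c.startswith(("x_", "c_"))]]
        est = BestSubsetsSmearingRegressor().fit(X, tn["median_mgL"].to_numpy())
        assert {"x_1", "x_2"} <= set(est.selected_predictors_)
        assert est.smearing_factor_ >= 1.0
        assert est.r2_ > 0.8
        pred = est.predict(X)
        assert np.all(pred > 0)

    def test_sklearn_params_protocol(self):
        est = BestSubsetsSmearingRegressor(max_exhaustive=6, selection_rule="cp_le_p")
        cl = clone(est)
        assert cl.get_params() == {"max_exhaustive": 6, "selection_rule": "cp_le_p"}
        cl.set_params(selection_rule="min_cp")
        assert cl.selection_rule == "min_cp"

    def test_nonpositive_response_rejected(self):
        X = pd.DataFrame({"x_1": np.arange(30, dtype=float)})
        with pytest.raises(ValueError, match="positive"):
            BestSubsetsSmearingRegressor().fit(X, np.linspace(-1, 1, 30))

    def test_predict_before_fit_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            BestSubsetsSmearingRegressor().predict(pd.DataFrame({"x_1": [1.0]}))
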