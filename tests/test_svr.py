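"""Epsilon-SVR fit/predict contracts, CV fitness, and the tuning loop."""

import numpy as np
import pandas as pd
import pytest

from besco import (
    EvalProtocol,
    HyperparamSpace,
    SvrFitConfig,
    SvrHyperparams,
    SVRTuner,
    budget_config,
    gen_cohort,
    hyperparam_fitness,
    svr_fit,
    svr_predict,
    tune_svr,
)
from besco.metrics import rmse


@pytest.fixture(scope="module")
def sine_data():
    x = np.linspace(0.0, 2.0 * np.pi, 50)[:, None]
    return x, np.sin(x).ravel()


class TestSvrFit:
    def test_constant_target_predicts_constant(self):
        X = np.arange(6.0)[:, None]
        model = svr_fit(X, np.full(6, 4.2), SvrHyperparams(10.0, 0.01, 1.0))
        np.testing.assert_allclose(model.predict(X), 4.2, atol=0.01 + 1e-3)

    def test_single_point_interpolation(self):
        model = svr_fit(np.array([[1.0]]), np.array([2.0]), SvrHyperparams(10.0, 0.1, 1.0))
        assert abs(model.predict(np.array([[1.0]]))[0] - 2.0) <= 0.1 + 1e-6

    def test_high_capacity_sine_fit(self, sine_data):
        X, y = sine_data
        model = svr_fit(X, y, SvrHyperparams(10000.0, 0.001, 10.0))
        assert rmse(y, model.predict(X)) <= 0.01

    def test_squared_loss_variant_fits(self, sine_data):
        X, y = sine_data
        model = svr_fit(X, y, SvrHyperparams(100.0, 0.01, 10.0),
                        SvrFitConfig(loss_exponent=2))
        assert rmse(y, model.predict(X)) <= 0.05
        assert model.n_support == X.shape[0]  # dense representer solution

    def test_slack_summary_nonnegative(self, sine_data):
        X, y = sine_data
        model = svr_fit(X, y, SvrHyperparams(10.0, 0.2, 1.0))
        assert model.slack_max >= model.slack_mean >= 0.0

    def test_rejects_non_finite_inputs(self):
        with pytest.raises(ValueError):
            svr_fit(np.array([[np.nan]]), np.array([1.0]), SvrHyperparams(1, 0.1, 1))
        with pytest.raises(ValueError):
            svr_fit(np.array([[1.0]]), np.array([np.inf]), SvrHyperparams(1, 0.1, 1))

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            SvrHyperparams(C=-1.0, eps_tube=0.1, gamma_kernel=1.0)
        with pytest.raises(ValueError):
            SvrHyperparams(C=1.0, eps_tube=-0.1, gamma_kernel=1.0)
        with pytest.raises(ValueError):
            SvrFitConfig(loss_exponent=3)


class TestSvrPredict:
    def test_row_permutation_permutes_predictions(self, sine_data):
        X, y = sine_data
        model = svr_fit(X, y, SvrHyperparams(100.0, 0.01, 5.0))
        perm = np.random.default_rng(0).permutation(X.shape[0])
        np.testing.assert_allclose(
            svr_predict(model, X[perm]), svr_predict(model, X)[perm]
        )

    def test_duplicate_rows_identical_predictions(self, sine_data):
        X, y = sine_data
        model = svr_fit(X, y, SvrHyperparams(100.0, 0.01, 5.0))
        dup = np.vstack([X[3], X[3]])
        p = svr_predict(model, dup)
        assert p[0] == p[1]

    def test_dimension_mismatch_raises(self, sine_data):
        X, y = sine_data
        model = svr_fit(X, y, SvrHyperparams(100.0, 0.01, 5.0))
        with pytest.raises(ValueError):
            svr_predict(model, np.zeros((3, 2)))


class TestHyperparamFitness:
    def test_learnable_constant_target_near_zero(self):
        X = np.linspace(0, 1, 24)[:, None]
        y = np.full(24, 7.0)
        fit = hyperparam_fitness(X, y, EvalProtocol(k=4, seed=0),
                                 SvrHyperparams(10.0, 0.01, 1.0), scale_target=False)
        assert fit <= 0.01 + 1e-3

    def test_deterministic_given_seed(self, small_cohort):
        X = small_cohort[["ACE", "sex"]].to_numpy()
        y = small_cohort["sIL2R"].to_numpy()
        params = SvrHyperparams(2000.0, 0.2, 2.0)
        a = hyperparam_fitness(X, y, EvalProtocol(seed=5), params)
        b = hyperparam_fitness(X, y, EvalProtocol(seed=5), params)
        assert a == b

    def test_two_fold_matches_manual_average(self):
        """2-fold CV fitness equals the hand-averaged per-fold RMSE."""
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, size=(12, 1))
        y = 2.0 * X.ravel() + rng.normal(0, 0.05, 12)
        params = SvrHyperparams(10.0, 0.01, 1.0)
        protocol = EvalProtocol(k=2, seed=3)
        got = hyperparam_fitness(X, y, protocol, params,
                                 standardize=False, scale_target=False)

        fold_rmses = []
        for tr, va in protocol.splits(12):
            model = svr_fit(X[tr], y[tr], params)
            fold_rmses.append(rmse(y[va], model.predict(X[va])))
        assert got == pytest.approx(np.mean(fold_rmses), abs=1e-12)

    def test_holdout_scheme(self, small_cohort):
        X = small_cohort[["ACE", "sex"]].to_numpy()
        y = small_cohort["sIL2R"].to_numpy()
        fit = hyperparam_fitness(X, y, EvalProtocol(scheme="holdout", seed=1),
                                 SvrHyperparams(2000.0, 0.2, 2.0))
        assert np.isfinite(fit) and fit >= 0

    def test_folds_partition_rows(self):
        protocol = EvalProtocol(k=5, seed=9)
        seen = []
        for tr, va in protocol.splits(23):
            seen.extend(va.tolist())
            assert set(tr).isdisjoint(va)
        assert sorted(seen) == list(range(23))

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            EvalProtocol(scheme="bootstrap")
        with pytest.raises(ValueError):
            EvalProtocol(k=1)


@pytest.fixture(scope="module")
def tuned(small_cohort):
    X = small_cohort[["ACE", "sex"]].to_numpy()
    y = small_cohort["sIL2R"].to_numpy()
    return tune_svr(X, y, optimizer="bes-co",
                    optimizer_config=budget_config("bes-co", 5, 3), seed=4)


class TestTuneSvr:
    def test_best_params_inside_box(self, tuned):
        assert HyperparamSpace().contains(tuned.best_params)

    def test_trace_non_increasing_and_matches_best(self, tuned):
        assert (np.diff(tuned.trace) <= 0).all()
        assert tuned.best_fitness == tuned.trace[-1]
        assert tuned.best_fitness <= tuned.trace[0]

    def test_final_model_refit_predicts_in_original_units(self, tuned, small_cohort):
        X = small_cohort[["ACE", "sex"]].to_numpy()
        preds = tuned.model.predict(X)
        assert np.isfinite(preds).all()
        # original-unit predictions live on the sIL-2R scale, not z-scores
        assert preds.mean() > 100.0

    def test_unknown_optimizer_raises(self, small_cohort):
        X = small_cohort[["ACE", "sex"]].to_numpy()
        y = small_cohort["sIL2R"].to_numpy()
        with pytest.raises(ValueError, match="unknown optimizer"):
            tune_svr(X, y, optimizer="simplex", seed=0)

    def test_log_c_search_stays_in_box(self, small_cohort):
        X = small_cohort[["ACE", "sex"]].to_numpy()
        y = small_cohort["sIL2R"].to_numpy()
        res = tune_svr(X, y, optimizer="bes",
                       optimizer_config=budget_config("bes", 4, 2), seed=2, log_c=True)
        assert HyperparamSpace().contains(res.best_params)


class TestModelObjects:
    def test_from_dataframe_and_summary(self, small_cohort):
        tuner = SVRTuner.from_dataframe(small_cohort)
        results = tuner.fit(optimizer="bes", pop_size=4, max_iter=2, seed=1)
        text = results.summary()
        assert "C (penalty)" in text and "CV RMSE" in text
        assert results.cv_rmse >= 0
        assert results.trace_frame().shape[1] == 2

    def test_from_dataframe_missing_column(self):
        df = pd.DataFrame({"ACE": [1.0, 2.0], "sex": [0, 1]})
        with pytest.raises(ValueError, match="missing column"):
            SVRTuner.from_dataframe(df)

    def test_results_reproducible_for_seed(self, small_cohort):
        tuner = SVRTuner.from_dataframe(small_cohort)
        a = tuner.fit(optimizer="bes", pop_size=4, max_iter=2, seed=9)
        b = tuner.fit(optimizer="bes", pop_size=4, max_iter=2, seed=9)
        assert a.best_params == b.best_params
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_space_table2_defaults(self):
        space = HyperparamSpace()
        assert space.c_range == (1000.0, 10000.0)
        assert space.eps_range == (0.001, 1.0)
        assert space.gamma_range == (1.0, 20.0)
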