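"""Mixed model, cross-validation harness, network, and total-effect FI."""

import numpy as np
import pandas as pd
import pytest

from regaze.models import (CVConfig, NNSpec, correlation_table,
                           fit_least_squares, fit_neural_net,
                           importance_report, lmm_session_test,
                           repeated_kfold, total_effect_importance,
                           ImportanceResult)


def _toy_xy(n=120, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 3))
    y = 2.0 * X[:, 0] - 1.0 * X[:, 1] + noise * rng.standard_normal(n)
    return X, y


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------


class TestLmm:
    def test_recovers_session_effect(self, small_long_table):
        res = lmm_session_test(small_long_table, "trt")
        assert abs(res.estimate_first_minus_last - 100.0) < 2 * res.se
        assert res.p < 0.001
        assert res.var_word > 0

    def test_zero_effect_type_one_rate(self):
        """Under a null generator, |t| < 2 in at least 90% of simulations."""
        rng = np.random.default_rng(42)
        calm = 0
        n_sim = 100
        for _ in range(n_sim):
            rows = []
            for w in range(30):
                base = rng.normal(500, 60)
                for ses in ("first", "last"):
                    rows.append({"sonnet_id": "sA", "line_no": 1, "word_no": w,
                                 "session": ses,
                                 "trt": base + rng.normal(0, 30)})
            res = lmm_session_test(pd.DataFrame(rows), "trt")
            calm += abs(res.tvalue) < 2
        assert calm >= 0.9 * n_sim

    def test_collapses_to_paired_t_without_word_variance(self):
        """With no between-word variance the fixed effect equals the mean
        paired difference."""
        rng = np.random.default_rng(9)
        rows = []
        diffs = []
        for w in range(40):
            first = rng.normal(500, 40)
            last = rng.normal(400, 40)
            diffs.append(first - last)
            rows.append({"sonnet_id": "sA", "line_no": 1, "word_no": w,
                         "session": "first", "trt": first})
            rows.append({"sonnet_id": "sA", "line_no": 1, "word_no": w,
                         "session": "last", "trt": last})
        res = lmm_session_test(pd.DataFrame(rows), "trt")
        assert res.estimate_first_minus_last == pytest.approx(
            np.mean(diffs), rel=1e-6)

    def test_missing_session_errors(self, small_long_table):
        first_only = small_long_table[small_long_table.session == "first"]
        with pytest.raises(ValueError):
            lmm_session_test(first_only, "trt")


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------


class TestRepeatedKFold:
    def test_noiseless_linear_perfect(self):
        X, y = _toy_xy(noise=0.0)
        s = repeated_kfold(X, y, CVConfig(k=5, reps=2, family="least_squares"))
        assert s.mean_test_r2 == pytest.approx(1.0, abs=1e-10)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((202, 9))
        y = rng.standard_normal(202)
        s = repeated_kfold(X, y, CVConfig(k=10, reps=10,
                                          family="least_squares"))
        assert s.mean_test_r2 <= 0.05
        assert s.mean_test_r2 <= s.mean_train_r2

    def test_whole_data_ols_matches_normal_equations(self):
        """The harness's R^2 for a full-data OLS fit equals the closed form."""
        X, y = _toy_xy(noise=0.5)
        model = fit_least_squares(X, y)
        pred = model.predict(X)
        r2_harness = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        A = np.column_stack([np.ones(len(X)), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        r2_closed = 1 - np.sum((y - A @ beta) ** 2) / np.sum(
            (y - y.mean()) ** 2)
        assert r2_harness == pytest.approx(r2_closed, abs=1e-10)

    def test_folds_partition_rows(self):
        from sklearn.model_selection import KFold
        kf = KFold(n_splits=10, shuffle=True, random_state=0)
        seen = np.zeros(202, dtype=int)
        for _, te in kf.split(np.zeros((202, 1))):
            seen[te] += 1
        assert (seen == 1).all()

    def test_invalid_configs(self):
        X, y = _toy_xy(n=15)
        with pytest.raises(ValueError):
            repeated_kfold(X, y, CVConfig(k=10))  # folds of 1 row
        with pytest.raises(ValueError):
            CVConfig(k=1)
        with pytest.raises(ValueError):
            CVConfig(family="forest")

    def test_seed_reproducibility(self):
        X, y = _toy_xy(noise=1.0)
        cfg = CVConfig(k=5, reps=2, seed=7, family="neural_net",
                       nn=NNSpec(restarts=2, max_iter=150))
        a = repeated_kfold(X, y, cfg)
        b = repeated_kfold(X, y, cfg)
        assert a.mean_test_r2 == b.mean_test_r2
        assert a.sd_test_r2 == b.sd_test_r2


# ---------------------------------------------------------------------------
# neural net
# ---------------------------------------------------------------------------


class TestNeuralNet:
    def test_recovers_linear_signal(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((300, 2))
        y = 3.0 * X[:, 0] + rng.standard_normal(300)
        nn = repeated_kfold(X, y, CVConfig(k=5, reps=2, family="neural_net"))
        ols = repeated_kfold(X, y, CVConfig(k=5, reps=2,
                                            family="least_squares"))
        assert abs(nn.mean_test_r2 - ols.mean_test_r2) < 0.05

    def test_beats_least_squares_on_interaction(self):
        """y = x1*x2 has no linear signal; the network must find it."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((500, 2))
        y = X[:, 0] * X[:, 1]
        nn = repeated_kfold(X, y, CVConfig(k=5, reps=3, seed=1,
                                           family="neural_net"))
        ols = repeated_kfold(X, y, CVConfig(k=5, reps=3, seed=1,
                                            family="least_squares"))
        assert nn.mean_test_r2 - ols.mean_test_r2 > 0.3

    def test_same_seed_identical_weights(self):
        X, y = _toy_xy(noise=0.3)
        a = fit_neural_net(X, y, NNSpec(seed=5, restarts=2))
        b = fit_neural_net(X, y, NNSpec(seed=5, restarts=2))
        assert np.array_equal(a.W1, b.W1)
        assert np.array_equal(a.w2, b.w2)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            NNSpec(hidden_units=0)
        with pytest.raises(ValueError):
            NNSpec(weight_decay=-1)

    def test_matches_sklearn_mlp_fit_quality(self):
        """Independent cross-check: our L-BFGS tanh net reaches the same
        training fit as sklearn's MLPRegressor with matched architecture."""
        from sklearn.neural_network import MLPRegressor
        import warnings

        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 3))
        y = np.tanh(X[:, 0]) + 0.5 * X[:, 1] + 0.1 * rng.standard_normal(200)
        ours = fit_neural_net(X, y, NNSpec(seed=0, weight_decay=1e-4,
                                           restarts=5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = MLPRegressor(hidden_layer_sizes=(3,), activation="tanh",
                               alpha=1e-4, solver="lbfgs", max_iter=2000,
                               random_state=0).fit(X, y)
        sst = np.sum((y - y.mean()) ** 2)
        r2_ours = 1 - np.sum((y - ours.predict(X)) ** 2) / sst
        r2_ref = 1 - np.sum((y - ref.predict(X)) ** 2) / sst
        assert abs(r2_ours - r2_ref) < 0.02


# ---------------------------------------------------------------------------
# total-effect importance
# ---------------------------------------------------------------------------


class _Additive:
    def predict(self, A):
        A = np.asarray(A)
        return 2.0 * A[:, 0] + A[:, 1]


class TestTotalEffect:
    def test_additive_independent_matches_sobol(self):
        """Analytic total indices 4/5 and 1/5 for y = 2x1 + x2."""
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((4000, 2)), columns=["a", "b"])
        res = total_effect_importance(_Additive(), X, n_mc=10_000, seed=1)
        assert res.fi[0] == pytest.approx(0.8, abs=0.03)
        assert res.fi[1] == pytest.approx(0.2, abs=0.03)

    def test_unused_predictor_near_zero(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((2000, 3)),
                         columns=["a", "b", "junk"])
        res = total_effect_importance(_Additive(), X, n_mc=5000, seed=2)
        assert res.fi[2] < 0.02

    def test_symmetric_duplicates_get_equal_fi(self):
        class Sym:
            def predict(self, A):
                A = np.asarray(A)
                return A[:, 0] + A[:, 1]

        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((3000, 2)), columns=["a", "b"])
        res = total_effect_importance(Sym(), X, n_mc=5000, seed=3)
        assert res.fi[0] == pytest.approx(res.fi[1], abs=0.02)

    def test_constant_model_errors(self):
        class Const:
            def predict(self, A):
                return np.zeros(len(np.asarray(A)))

        X = pd.DataFrame(np.random.default_rng(0).standard_normal((100, 2)))
        with pytest.raises(ValueError, match="variance"):
            total_effect_importance(Const(), X, n_mc=500, seed=0)

    def test_clipped_to_unit_interval_and_se_reported(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((500, 2)), columns=["a", "b"])
        res = total_effect_importance(_Additive(), X, n_mc=500, seed=4)
        assert all(0 <= v <= 1 for v in res.fi)
        assert all(s >= 0 for s in res.se)


class TestImportanceReport:
    def test_flags_and_ranking(self):
        res = ImportanceResult(("a", "b"), (0.52, 0.09), (0.01, 0.01))
        rep = importance_report(res)
        assert list(rep["predictor"]) == ["a", "b"]
        assert list(rep["important"]) == [True, False]

    def test_exact_threshold_not_important(self):
        res = ImportanceResult(("a",), (0.1,), (0.0,))
        assert importance_report(res)["important"].tolist() == [False]

    def test_all_below_threshold(self):
        res = ImportanceResult(("a", "b"), (0.05, 0.02), (0.0, 0.0))
        assert not importance_report(res)["important"].any()


class TestCorrelationTable:
    def test_collinear_pair_unit(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        assert correlation_table(df).loc["x", "y"] == pytest.approx(1.0)

    def test_identity_holds_for_trt_decomposition(self):
        rng = np.random.default_rng(0)
        gd = rng.gamma(8, 40, 500)
        rt = rng.gamma(4, 60, 500)
        df = pd.DataFrame({"trt": gd + rt, "sum": gd + rt})
        assert correlation_table(df).loc["trt", "sum"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((10_000, 2)), columns=["a", "b"])
        assert abs(correlation_table(df).loc["a", "b"]) < 0.05

    def test_constant_column_warns_nan(self, caplog):
        df = pd.DataFrame({"x": [1.0, 2, 3], "c": [5.0, 5, 5]})
        out = correlation_table(df)
        assert np.isnan(out.loc["x", "c"])
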