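"""Preprocessing, SNR filtering, and the two linear trainers."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.linear_model import Ridge
from sklearn.svm import LinearSVC

import enzyres as ez
from enzyres.readout import NormStats, fit_linear_classifier, fit_ridge


def df(arr, cols=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"f{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


class TestNormalization:
    def test_population_standardization_hand_values(self):
        Z, stats = ez.normalize_fit_transform(df([[1.0], [2.0], [3.0]]))
        assert Z["f0"].tolist() == pytest.approx([-1.224744871, 0.0, 1.224744871])

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(0)
        X = df(rng.normal(size=(50, 3)))
        Z, _ = ez.normalize_fit_transform(X)
        Z2, _ = ez.normalize_fit_transform(Z)
        assert np.allclose(Z.to_numpy(), Z2.to_numpy())

    def test_constant_column_dropped_with_warning(self):
        X = df([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            Z, stats = ez.normalize_fit_transform(X)
        assert stats.kept == ["f0"] and list(Z.columns) == ["f0"]

    def test_statistics_reusable_on_held_out_rows(self):
        rng = np.random.default_rng(1)
        X = df(rng.normal(size=(30, 4)))
        _, stats = ez.normalize_fit_transform(X.iloc[:20])
        held = stats.transform(X.iloc[20:])
        manual = (X.iloc[20:][stats.kept] - stats.mean) / stats.sd
        assert np.allclose(held.to_numpy(), manual.to_numpy())


class TestSNRFilter:
    def test_constant_feature_removed(self):
        X = df(np.ones((8, 1)))
        groups = np.repeat([0, 1], 4)
        assert ez.snr_filter(X, groups) == []

    def test_pure_group_signal_retained(self):
        # zero within-group scatter, distinct group means -> infinite SNR
        X = df(np.repeat([[0.0], [1.0]], 4, axis=0))
        groups = np.repeat([0, 1], 4)
        assert ez.snr_filter(X, groups) == ["f0"]

    def test_iid_noise_removed_about_half_the_time(self):
        # under the null, SNR concentrates near 1: the removal rate over
        # many simulated noise features sits near 50%
        rng = np.random.default_rng(42)
        groups = np.repeat(np.arange(20), 4)
        X = df(rng.normal(size=(80, 400)))
        kept = ez.snr_filter(X, groups)
        rate = 1.0 - len(kept) / 400
        assert 0.35 < rate < 0.65

    def test_singleton_group_skipped_with_warning(self):
        X = df(np.arange(9.0).reshape(9, 1))
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2])  # group 2 has one member
        with pytest.warns(UserWarning, match="single-replicate"):
            ez.snr_filter(X, groups)


class TestRidge:
    def test_exact_recovery_without_regularization(self):
        rng = np.random.default_rng(3)
        X = df(rng.normal(size=(40, 4)))
        w_true = np.array([1.0, -2.0, 0.5, 3.0])
        y = X.to_numpy() @ w_true + 0.7
        model = fit_ridge(X, y, alpha=0.0)
        assert model.weights.to_numpy() == pytest.approx(w_true, abs=1e-9)
        assert model.intercept == pytest.approx(0.7, abs=1e-9)

    def test_heavy_shrinkage_predicts_the_mean(self):
        rng = np.random.default_rng(4)
        X = df(rng.normal(size=(30, 3)))
        y = rng.normal(size=30)
        model = fit_ridge(X, y, alpha=1e12)
        assert np.abs(model.weights).max() < 1e-8
        assert model.predict(X) == pytest.approx(np.full(30, y.mean()), abs=1e-6)

    def test_singular_system_requires_regularization(self):
        X = df(np.ones((10, 2)) * [[1.0, 2.0]] * 10)  # collinear columns
        with pytest.raises(np.linalg.LinAlgError, match="alpha"):
            fit_ridge(X, np.arange(10.0), alpha=0.0)

    def test_matches_iterative_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        X = df(rng.normal(size=(20, 5)))
        y = rng.normal(size=20)
        alpha = 0.8
        model = fit_ridge(X, y, alpha=alpha)

        A = X.to_numpy()
        def objective(theta):
            w, b = theta[:5], theta[5]
            r = y - A @ w - b
            return r @ r + alpha * w @ w
        res = minimize(objective, np.zeros(6), method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 5000})
        assert model.weights.to_numpy() == pytest.approx(res.x[:5], abs=1e-6)
        assert model.intercept == pytest.approx(res.x[5], abs=1e-6)

    def test_matches_reference_library(self):
        rng = np.random.default_rng(6)
        X = df(rng.normal(size=(25, 6)))
        y = rng.normal(size=25)
        model = fit_ridge(X, y, alpha=1.0)
        ref = Ridge(alpha=1.0).fit(X.to_numpy(), y)
        assert model.weights.to_numpy() == pytest.approx(ref.coef_, abs=1e-8)
        assert model.intercept == pytest.approx(ref.intercept_, abs=1e-8)


class TestLinearClassifier:
    def test_separable_data_fit_perfectly(self):
        rng = np.random.default_rng(7)
        X0 = rng.normal(loc=-2.0, size=(20, 2))
        X1 = rng.normal(loc=+2.0, size=(20, 2))
        X = df(np.vstack([X0, X1]))
        y = np.repeat([0, 1], 20)
        model = fit_linear_classifier(X, y, C=1.0)
        assert np.array_equal(model.predict(X), y)

    def test_single_class_rejected(self):
        X = df(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError, match="single class"):
            fit_linear_classifier(X, np.zeros(10, dtype=int))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_reference_solver(self, seed):
        rng = np.random.default_rng(seed)
        X = df(rng.normal(size=(30, 10)))
        w = rng.normal(size=10)
        y = (X.to_numpy() @ w + 0.3 * rng.normal(size=30) > 0).astype(int)
        model = fit_linear_classifier(X, y, C=1.0)
        ref = LinearSVC(C=1.0, loss="squared_hinge", tol=1e-8, max_iter=100000)
        ref.fit(X.to_numpy(), y)
        assert np.array_equal(model.predict(X), ref.predict(X.to_numpy()))
        assert model.weights.to_numpy() == pytest.approx(ref.coef_[0], abs=1e-3)

    def test_held_out_score_is_chance_under_label_permutation(self):
        # labels independent of features: predictions on fresh rows from
        # the same distribution carry no skill
        rng = np.random.default_rng(8)
        scores = []
        for _ in range(100):
            X = df(rng.normal(size=(48, 3)))
            y = rng.integers(0, 2, size=48)
            if len(np.unique(y[:24])) < 2:
                continue
            model = fit_linear_classifier(X.iloc[:24], y[:24], C=1.0)
            pred = model.predict(X.iloc[24:])
            scores.append(ez.transform_phi(ez.phi_score(
                *_confusion(y[24:], pred))))
        mean = np.mean(scores)
        se = np.std(scores, ddof=1) / np.sqrt(len(scores))
        assert abs(mean - 0.5) <= 3 * se


def _confusion(y, p):
    from enzyres.evaluation import confusion
    return confusion(y, p)


class TestRegularizationPaths:
    def test_ridge_norm_monotone_in_alpha(self):
        rng = np.random.default_rng(9)
        X = df(rng.normal(size=(40, 6)))
        y = rng.normal(size=40)
        norms = [np.linalg.norm(fit_ridge(X, y, alpha=a).weights)
                 for a in (0.01, 0.1, 1.0, 10.0, 100.0)]
        assert norms == sorted(norms, reverse=True)

    def test_classifier_norm_monotone_in_C(self):
        rng = np.random.default_rng(10)
        X = df(rng.normal(size=(40, 4)))
        y = (X["f0"] + 0.5 * rng.normal(size=40) > 0).astype(int).to_numpy()
        norms = [np.linalg.norm(fit_linear_classifier(X, y, C=c).weights)
                 for c in (0.01, 0.1, 1.0, 10.0)]
        assert norms == sorted(norms)


class TestModelApplication:
    def test_zero_weights_predict_the_intercept(self):
        model = ez.ReadoutModel(weights=pd.Series([0.0, 0.0], index=["a", "b"]),
                                intercept=2.5, mode="regressor", regularization=1.0)
        X = df(np.random.default_rng(0).normal(size=(5, 2)), cols=["a", "b"])
        assert model.predict(X) == pytest.approx(np.full(5, 2.5))

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(11)
        X = df(rng.normal(size=(30, 5)))
        y = (rng.normal(size=30) > 0).astype(int)
        a = ez.train_readout(X, y, mode="classifier")
        b = ez.train_readout(X, y, mode="classifier")
        assert a.weights.equals(b.weights) and a.intercept == b.intercept

    def test_feature_perturbation_scales_with_weight_over_sd(self):
        rng = np.random.default_rng(12)
        X = df(rng.normal(size=(30, 3)))
        y = rng.normal(size=30)
        model = ez.train_readout(X, y, mode="regressor", alpha=0.5)
        x0 = X.iloc[[0]].copy()
        x1 = x0.copy()
        delta = 0.37
        x1["f1"] += delta
        got = model.predict(x1)[0] - model.predict(x0)[0]
        expected = model.weights["f1"] * delta / model.norm.sd["f1"]
        assert got == pytest.approx(expected, rel=1e-9)

    def test_missing_feature_errors_with_names(self):
        model = ez.ReadoutModel(
            weights=pd.Series([1.0], index=["a"]), intercept=0.0,
            mode="regressor", regularization=1.0,
            norm=NormStats(mean=pd.Series({"a": 0.0}), sd=pd.Series({"a": 1.0}),
                           kept=["a"]))
        with pytest.raises(KeyError, match="a"):
            model.predict(df(np.zeros((2, 1)), cols=["b"]))

    def test_no_leakage_from_held_out_rows(self):
        rng = np.random.default_rng(13)
        X = df(rng.normal(size=(40, 4)))
        y = rng.normal(size=40)
        model = ez.train_readout(X.iloc[:30], y[:30], mode="regressor")
        corrupted = X.copy()
        corrupted.iloc[30:] = 1e6  # held-out rows corrupted after fitting
        model2 = ez.train_readout(corrupted.iloc[:30], y[:30], mode="regressor")
        # corrupting held-out rows by 1e6 would shift the mean by ~3e5 if
        # statistics leaked; allow only summation-order noise
        assert np.allclose(model.norm.mean, model2.norm.mean, atol=1e-12)
        assert np.allclose(model.weights, model2.weights, atol=1e-9)

    def test_json_round_trip_is_exact(self):
        rng = np.random.default_rng(14)
        X = df(rng.normal(size=(20, 3)))
        y = rng.normal(size=20)
        model = ez.train_readout(X, y, mode="regressor")
        back = ez.ReadoutModel.from_json(model.to_json())
        assert back.weights.equals(model.weights)
        assert back.intercept == model.intercept
        assert back.norm.mean.equals(model.norm.mean)
        assert np.array_equal(back.predict(X), model.predict(X))
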