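import numpy as np
import pandas as pd
import pytest

from trainperf.models import (
    ElasticNetModel,
    EstimatorSpec,
    PCRModel,
    RandomForestModel,
    fit_enet,
    fit_pcr,
    fit_rf,
    kaiser_select,
)


def standardise(X):
    M = X.to_numpy(dtype=float)
    return (M - M.mean(0)) / M.std(0, ddof=1)


class TestElasticNet:
    def test_lambda_zero_equals_ols(self, toy_xy):
        X, y = toy_xy
        model = fit_enet(X, y, alpha=0.5, lam=0.0)
        Z = standardise(X)
        A = np.column_stack([np.ones(len(y)), Z])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), A @ beta, atol=1e-6)

    def test_full_lasso_shrinkage(self, toy_xy):
        X, y = toy_xy
        model = fit_enet(X, y, alpha=1.0, lam=1e6)
        assert np.all(model.coef_ == 0.0)
        assert model.intercept_ == pytest.approx(np.mean(y))

    def test_ridge_closed_form(self, toy_xy):
        # objective 1/2||y-Zb||^2 + lam ||b||^2  =>  b = (Z'Z + 2 lam I)^-1 Z'(y - ybar)
        X, y = toy_xy
        lam = 3.7
        model = fit_enet(X, y, alpha=0.0, lam=lam)
        Z = standardise(X)
        yc = y - y.mean()
        beta = np.linalg.solve(Z.T @ Z + 2 * lam * np.eye(Z.shape[1]), Z.T @ yc)
        np.testing.assert_allclose(model.coef_, beta, atol=1e-8)
        assert model.intercept_ == pytest.approx(np.mean(y))

    def test_training_error_monotone_in_lambda(self, toy_xy):
        X, y = toy_xy
        errors = []
        for lam in [0.0, 0.1, 1.0, 10.0, 100.0]:
            m = fit_enet(X, y, alpha=0.5, lam=lam)
            errors.append(np.sum((y - m.predict(X)) ** 2))
        assert all(a <= b + 1e-9 for a, b in zip(errors, errors[1:]))

    @pytest.mark.parametrize("alpha, lam", [(-0.1, 1.0), (1.1, 1.0), (0.5, -1.0)])
    def test_invalid_hyperparams(self, toy_xy, alpha, lam):
        X, y = toy_xy
        with pytest.raises(ValueError):
            fit_enet(X, y, alpha=alpha, lam=lam)

    def test_standardisation_from_training_rows_only(self, toy_xy):
        X, y = toy_xy
        train = X.iloc[:30]
        model = fit_enet(train, y[:30], alpha=0.5, lam=0.1)
        center, scale = model.center_.copy(), model.scale_.copy()
        # mutating rows outside the training window cannot touch stored params
        X.iloc[30:] += 1e6
        refit = fit_enet(X.iloc[:30], y[:30], alpha=0.5, lam=0.1)
        np.testing.assert_array_equal(refit.center_, center)
        np.testing.assert_array_equal(refit.scale_, scale)

    def test_zero_variance_column_dropped(self, toy_xy):
        X, y = toy_xy
        X = X.copy()
        X["X6"] = 1.0
        model = fit_enet(X, y, alpha=0.5, lam=0.1)
        assert len(model.coef_) == 5
        assert np.all(np.isfinite(model.predict(X)))

    def test_unseen_athlete_level_rejected(self):
        X = pd.DataFrame({"X1": [1.0, 2.0, 3.0, 4.0], "X19": ["a", "a", "b", "b"]})
        y = np.array([1.0, 2.0, 3.0, 4.0])
        model = fit_enet(X, y, alpha=0.5, lam=0.1)
        bad = pd.DataFrame({"X1": [1.0], "X19": ["c"]})
        with pytest.raises(KeyError, match="unseen"):
            model.predict(bad)

    def test_missing_column_named_in_error(self, toy_xy):
        X, y = toy_xy
        model = fit_enet(X, y, alpha=0.5, lam=0.1)
        with pytest.raises(KeyError, match="X5"):
            model.predict(X.drop(columns=["X5"]))


class TestKaiser:
    @pytest.mark.parametrize(
        "evals, expected", [([2.4, 1.2, 0.8, 0.6], 2), ([0.99, 0.98], 1), ([3.0], 1)]
    )
    def test_rule(self, evals, expected):
        assert kaiser_select(evals) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kaiser_select([])


class TestPCR:
    def test_all_components_equal_ols(self, toy_xy):
        X, y = toy_xy
        model = fit_pcr(X, y, n_components=X.shape[1])
        Z = standardise(X)
        A = np.column_stack([np.ones(len(y)), Z])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), A @ beta, atol=1e-8)

    def test_planted_single_factor_retains_one_component(self):
        rng = np.random.default_rng(8)
        f = rng.normal(size=200)
        loadings = rng.normal(size=5)
        X = pd.DataFrame(
            np.outer(f, loadings) + 0.05 * rng.normal(size=(200, 5)),
            columns=[f"X{i}" for i in range(1, 6)],
        )
        y = f + 0.1 * rng.normal(size=200)
        model = fit_pcr(X, y)
        assert model.n_components_ == 1
        assert np.sum(model.eigenvalues_ > 1.0) == 1

    def test_loadings_orthonormal(self, toy_xy):
        X, y = toy_xy
        model = fit_pcr(X, y, n_components=3)
        np.testing.assert_allclose(
            model.loadings_.T @ model.loadings_, np.eye(3), atol=1e-10
        )

    def test_predict_matches_hand_projection_on_toy(self):
        X = pd.DataFrame({"X1": [0.0, 1.0, 2.0], "X2": [1.0, 3.0, 5.0]})
        y = np.array([1.0, 2.0, 4.0])
        model = fit_pcr(X, y, n_components=1)
        Z = standardise(X)
        scores = Z @ model.loadings_
        A = np.column_stack([np.ones(3), scores])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), A @ beta, atol=1e-10)

    def test_bad_component_count(self, toy_xy):
        X, y = toy_xy
        with pytest.raises(ValueError, match="n_components"):
            fit_pcr(X, y, n_components=99)


class TestRandomForest:
    def test_constant_target(self, toy_xy):
        X, _ = toy_xy
        y = np.full(len(X), 17.0)
        model = fit_rf(X, y, mtry=2, n_trees=25, seed=0)
        np.testing.assert_allclose(model.predict(X), 17.0)

    def test_prediction_is_mean_of_trees(self, toy_xy):
        X, y = toy_xy
        model = fit_rf(X, y, mtry=2, n_trees=30, seed=1)
        per_tree = model.tree_predictions(X)
        assert per_tree.shape == (30, len(X))
        np.testing.assert_allclose(model.predict(X), per_tree.mean(axis=0), rtol=1e-12)

    def test_seed_determinism(self, toy_xy):
        X, y = toy_xy
        p1 = fit_rf(X, y, mtry=3, n_trees=40, seed=9).predict(X)
        p2 = fit_rf(X, y, mtry=3, n_trees=40, seed=9).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_mtry_out_of_range(self, toy_xy):
        X, y = toy_xy
        with pytest.raises(ValueError, match="mtry"):
            fit_rf(X, y, mtry=99)

    def test_categorical_athlete_integer_coded(self):
        X = pd.DataFrame({"X1": np.arange(8.0), "X19": list("aabbccdd")})
        y = np.arange(8.0)
        model = fit_rf(X, y, mtry=1, n_trees=10, seed=0)
        assert np.all(np.isfinite(model.predict(X)))
        with pytest.raises(KeyError, match="unseen"):
            model.predict(pd.DataFrame({"X1": [0.0], "X19": ["z"]}))


class TestPersistence:
    def test_linear_models_roundtrip_through_json(self, toy_xy, tmp_path):
        from trainperf.models import load_model, save_model

        X, y = toy_xy
        for model in (fit_enet(X, y, alpha=0.3, lam=0.5), fit_pcr(X, y)):
            path = tmp_path / f"{type(model).__name__}.json"
            save_model(model, path)
            back = load_model(path)
            np.testing.assert_allclose(back.predict(X), model.predict(X), rtol=1e-12)

    def test_forest_roundtrip_through_sidecar(self, toy_xy, tmp_path):
        from trainperf.models import load_model, save_model

        X, y = toy_xy
        model = fit_rf(X, y, mtry=2, n_trees=15, seed=0)
        path = tmp_path / "forest.joblib"
        save_model(model, path)
        np.testing.assert_array_equal(load_model(path).predict(X), model.predict(X))


class TestEstimatorSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            EstimatorSpec("boost", "group")
        with pytest.raises(ValueError):
            EstimatorSpec("enet", "teamwise")
        with pytest.raises(ValueError):
            EstimatorSpec("dr", "individual", {"lam": 1.0})

    def test_regularisation_tiebreak_ordering(self):
        weak = EstimatorSpec("enet", "group", {"alpha": 0.2, "lam": 0.01})
        strong = EstimatorSpec("enet", "group", {"alpha": 0.2, "lam": 1.0})
        assert sorted([weak, strong], key=lambda s: s.regularisation_key())[0] is strong
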