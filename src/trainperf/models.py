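"""Regularised and ensemble regressors under one fit/predict contract.

Three families compete with the dose-response reference:

* **ENET** — elastic net with the objective
  ``min_b 1/2 ||y - Xb||^2 + lam * ((1 - alpha) ||b||_2^2 + alpha ||b||_1)``
  where ``alpha`` in [0, 1] mixes ridge (0) and lasso (1) and ``lam >= 0``
  scales the penalty.  The intercept is never penalised.  Internally this is
  mapped exactly onto scikit-learn's parameterisation
  (``alpha_sk = lam * (2 - alpha) / n``, ``l1_ratio = alpha / (2 - alpha)``),
  with closed-form Ridge for ``alpha = 0`` and plain least squares for
  ``lam = 0``.
* **PCR** — principal component regression: PCA of the standardised
  predictors, components retained by Kaiser's rule (correlation-matrix
  eigenvalue > 1), ordinary least squares on the retained scores.
* **RF** — a random forest of regression trees on bootstrap rows with
  ``mtry`` candidate variables per split; prediction is the mean over trees.

Linear families z-score every predictor using statistics of the *training*
rows only and one-hot-encode the athlete id; the forest consumes raw features
with an integer-coded athlete id.  An unseen athlete level at predict time is
a schema error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression, Ridge

__all__ = [
    "EstimatorSpec",
    "ElasticNetModel",
    "PCRModel",
    "RandomForestModel",
    "kaiser_select",
    "fit_enet",
    "fit_pcr",
    "fit_rf",
    "save_model",
    "load_model",
    "make_estimator",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EstimatorSpec:
    """A model family + mode + hyper-parameter setting, as used by the CV."""

    family: str  # enet | pcr | rf | dr
    mode: str = "group"  # individual | group
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("enet", "pcr", "rf", "dr"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.mode not in ("individual", "group"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.family == "dr" and self.hyperparams:
            raise ValueError("the dose-response model has no hyper-parameters")

    def label(self) -> str:
        hp = ",".join(f"{k}={v}" for k, v in sorted(self.hyperparams.items()))
        return f"{self.family}_{'G' if self.mode == 'group' else 'I'}({hp})"

    def regularisation_key(self):
        """Sort key used to break score ties in favour of more regularisation."""
        h = self.hyperparams
        if self.family == "enet":
            return (-h.get("lam", 0.0), -h.get("alpha", 0.0))
        if self.family == "rf":
            return (h.get("mtry") or np.inf,)
        return ()


def kaiser_select(eigenvalues) -> int:
    """Number of correlation-matrix eigenvalues strictly greater than 1.

    Falls back to 1 (with a log message) when no eigenvalue exceeds 1, so the
    regression always has at least one component.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue list")
    p = int(np.sum(ev > 1.0))
    if p == 0:
        logger.info("no eigenvalue exceeds 1; falling back to a single component")
        p = 1
    return p


class _TabularMixin:
    """Shared column bookkeeping: categorical encoding + standardisation."""

    def _split_columns(self, X: pd.DataFrame):
        cat = [c for c in X.columns if X[c].dtype == object or isinstance(X[c].dtype, pd.CategoricalDtype)]
        num = [c for c in X.columns if c not in cat]
        return num, cat

    def _check_columns(self, X: pd.DataFrame):
        for col in self.feature_names_in_:
            if col not in X.columns:
                raise KeyError(f"missing predictor column {col!r}")


class _LinearBase(_TabularMixin, BaseEstimator, RegressorMixin):
    """Standardise-then-regress scaffolding shared by ENET and PCR."""

    def _encode_fit(self, X: pd.DataFrame, y):
        self.feature_names_in_ = list(X.columns)
        num, cat = self._split_columns(X)
        self._num_cols = num
        self._cat_levels = {c: sorted(X[c].astype(str).unique()) for c in cat}
        M = self._raw_matrix(X)
        # training-rows-only standardisation (ddof=1 so that the covariance of
        # the standardised matrix is the correlation matrix)
        self.center_ = M.mean(axis=0)
        self.scale_ = M.std(axis=0, ddof=1) if len(M) > 1 else np.ones(M.shape[1])
        keep = self.scale_ > 0
        if not keep.all():
            dropped = [self._encoded_names[i] for i in np.flatnonzero(~keep)]
            logger.warning("dropping zero-variance column(s): %s", dropped)
        self._keep = keep
        Z = (M[:, keep] - self.center_[keep]) / self.scale_[keep]
        return Z, np.asarray(y, dtype=float)

    def _raw_matrix(self, X: pd.DataFrame) -> np.ndarray:
        cols = [X[c].to_numpy(dtype=float) for c in self._num_cols]
        names = list(self._num_cols)
        for c, levels in self._cat_levels.items():
            seen = set(levels)
            unknown = set(X[c].astype(str)) - seen
            if unknown:
                raise KeyError(
                    f"unseen level(s) {sorted(unknown)} in column {c!r} at predict time"
                )
            for lv in levels:
                cols.append((X[c].astype(str) == lv).to_numpy(dtype=float))
                names.append(f"{c}={lv}")
        self._encoded_names = names
        return np.column_stack(cols) if cols else np.empty((len(X), 0))

    def _encode_predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_columns(X)
        M = self._raw_matrix(X[self.feature_names_in_])
        return (M[:, self._keep] - self.center_[self._keep]) / self.scale_[self._keep]


class ElasticNetModel(_LinearBase):
    """Elastic-net linear model under the mixed L1/L2 objective above.

    Parameters
    ----------
    alpha : float in [0, 1]
        Mixing parameter: 0 = pure ridge, 1 = pure lasso.
    lam : float >= 0
        Overall penalty strength; 0 reduces to ordinary least squares.
    """

    def __init__(self, alpha: float = 0.5, lam: float = 0.01):
        self.alpha = alpha
        self.lam = lam

    def fit(self, X: pd.DataFrame, y):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        Z, y = self._encode_fit(X, y)
        n = len(y)
        if self.lam == 0.0:
            base = LinearRegression()
        elif self.alpha == 0.0:
            # min 1/2||y-Zb||^2 + lam||b||^2  ==  sklearn Ridge with alpha=2*lam
            base = Ridge(alpha=2.0 * self.lam, solver="svd")
        else:
            base = ElasticNet(
                alpha=self.lam * (2.0 - self.alpha) / n,
                l1_ratio=self.alpha / (2.0 - self.alpha),
                max_iter=100_000,
                tol=1e-10,
            )
        base.fit(Z, y)
        self.coef_ = np.asarray(base.coef_, dtype=float)
        self.intercept_ = float(base.intercept_)
        return self

    def predict(self, X: pd.DataFrame):
        Z = self._encode_predict(X)
        return Z @ self.coef_ + self.intercept_


class PCRModel(_LinearBase):
    """Principal component regression with Kaiser-rule component selection.

    ``n_components=None`` applies Kaiser's rule (eigenvalue of the predictor
    correlation matrix > 1); an integer forces that many components.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y):
        Z, y = self._encode_fit(X, y)
        n, d = Z.shape
        corr = (Z.T @ Z) / max(n - 1, 1)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        self.eigenvalues_ = evals[order]
        evecs = evecs[:, order]
        if self.n_components is None:
            p = kaiser_select(self.eigenvalues_)
        else:
            p = int(self.n_components)
            if not 1 <= p <= d:
                raise ValueError(f"n_components must lie in [1, {d}], got {p}")
        self.n_components_ = p
        self.loadings_ = evecs[:, :p]
        scores = Z @ self.loadings_
        A = np.column_stack([np.ones(n), scores])
        beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        return self

    def predict(self, X: pd.DataFrame):
        Z = self._encode_predict(X)
        return (Z @ self.loadings_) @ self.coef_ + self.intercept_


class RandomForestModel(_TabularMixin, BaseEstimator, RegressorMixin):
    """Random-forest regressor (bootstrap rows, ``mtry`` variables per split).

    ``mtry=None`` defaults to ``max(1, d // 3)``, the usual regression
    heuristic.  Only ``mtry`` and ``n_trees`` are tunable.
    """

    def __init__(self, mtry: int | None = None, n_trees: int = 500, seed: int = 0):
        self.mtry = mtry
        self.n_trees = n_trees
        self.seed = seed

    def _encode(self, X: pd.DataFrame, fitting: bool) -> np.ndarray:
        if fitting:
            self.feature_names_in_ = list(X.columns)
            num, cat = self._split_columns(X)
            self._num_cols, self._cat_cols = num, cat
            self._codes = {
                c: {lv: i for i, lv in enumerate(sorted(X[c].astype(str).unique()))}
                for c in cat
            }
        else:
            self._check_columns(X)
            X = X[self.feature_names_in_]
        cols = [X[c].to_numpy(dtype=float) for c in self._num_cols]
        for c in self._cat_cols:
            mapping = self._codes[c]
            vals = X[c].astype(str)
            unknown = set(vals) - set(mapping)
            if unknown:
                raise KeyError(f"unseen level(s) {sorted(unknown)} in column {c!r}")
            cols.append(vals.map(mapping).to_numpy(dtype=float))
        return np.column_stack(cols)

    def fit(self, X: pd.DataFrame, y):
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        M = self._encode(X, fitting=True)
        d = M.shape[1]
        mtry = max(1, d // 3) if self.mtry is None else int(self.mtry)
        if not 1 <= mtry <= d:
            raise ValueError(f"mtry must lie in [1, {d}], got {mtry}")
        self.mtry_ = mtry
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=mtry,
            bootstrap=True,
            random_state=self.seed,
        )
        self.forest_.fit(M, np.asarray(y, dtype=float))
        return self

    def predict(self, X: pd.DataFrame):
        return self.forest_.predict(self._encode(X, fitting=False))

    def tree_predictions(self, X: pd.DataFrame) -> np.ndarray:
        """Per-tree predictions, shape (n_trees, n_rows); their mean is predict()."""
        M = self._encode(X, fitting=False)
        return np.stack([t.predict(M) for t in self.forest_.estimators_])


def fit_enet(X, y, alpha: float, lam: float) -> ElasticNetModel:
    """Fit an elastic net at the given mixing/penalty values."""
    return ElasticNetModel(alpha=alpha, lam=lam).fit(X, y)


def fit_pcr(X, y, n_components: int | None = None) -> PCRModel:
    """Fit a principal component regression (Kaiser rule unless forced)."""
    return PCRModel(n_components=n_components).fit(X, y)


def fit_rf(X, y, mtry: int | None = None, n_trees: int = 500, seed: int = 0) -> RandomForestModel:
    """Fit a random-forest regressor."""
    return RandomForestModel(mtry=mtry, n_trees=n_trees, seed=seed).fit(X, y)


def save_model(model, path) -> None:
    """Persist a fitted model.

    Linear families are written as transparent JSON (hyper-parameters,
    standardisation statistics, coefficients, and PCR loadings); the random
    forest is written as a joblib binary sidecar, since trees have no useful
    flat-text form.
    """
    import json
    from pathlib import Path

    path = Path(path)
    if isinstance(model, RandomForestModel):
        import joblib

        joblib.dump(model, path)
        return
    common = {
        "feature_names": model.feature_names_in_,
        "num_cols": model._num_cols,
        "cat_levels": model._cat_levels,
        "center": model.center_.tolist(),
        "scale": model.scale_.tolist(),
        "keep": model._keep.tolist(),
        "coef": np.asarray(model.coef_).tolist(),
        "intercept": model.intercept_,
    }
    if isinstance(model, ElasticNetModel):
        payload = {"family": "enet", "alpha": model.alpha, "lam": model.lam, **common}
    elif isinstance(model, PCRModel):
        payload = {
            "family": "pcr",
            "n_components": model.n_components_,
            "loadings": model.loadings_.tolist(),
            "eigenvalues": model.eigenvalues_.tolist(),
            **common,
        }
    else:
        raise TypeError(f"cannot persist {type(model).__name__}")
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_model(path):
    """Load a model written by :func:`save_model`."""
    import json
    from pathlib import Path

    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (UnicodeDecodeError, json.JSONDecodeError):
        import joblib

        return joblib.load(path)
    if payload["family"] == "enet":
        model = ElasticNetModel(alpha=payload["alpha"], lam=payload["lam"])
    else:
        model = PCRModel(n_components=payload["n_components"])
        model.n_components_ = payload["n_components"]
        model.loadings_ = np.asarray(payload["loadings"])
        model.eigenvalues_ = np.asarray(payload["eigenvalues"])
    model.feature_names_in_ = payload["feature_names"]
    model._num_cols = payload["num_cols"]
    model._cat_levels = payload["cat_levels"]
    model.center_ = np.asarray(payload["center"])
    model.scale_ = np.asarray(payload["scale"])
    model._keep = np.asarray(payload["keep"], dtype=bool)
    model.coef_ = np.asarray(payload["coef"])
    model.intercept_ = payload["intercept"]
    return model


def make_estimator(spec: EstimatorSpec, loads=None, seed: int = 0):
    """Instantiate the estimator described by a spec (unfitted)."""
    h = dict(spec.hyperparams)
    if spec.family == "enet":
        return ElasticNetModel(alpha=h.get("alpha", 0.5), lam=h.get("lam", 0.01))
    if spec.family == "pcr":
        return PCRModel(n_components=h.get("n_components"))
    if spec.family == "rf":
        return RandomForestModel(
            mtry=h.get("mtry"), n_trees=h.get("n_trees", 500), seed=h.get("seed", seed)
        )
    if spec.family == "dr":
        from .dose_response import DoseResponseModel

        return DoseResponseModel(loads=loads, seed=seed)
    raise ValueError(f"unknown family {spec.family!r}")
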