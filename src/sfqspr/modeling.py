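"""Regression models, cross-validation, and the R-squared metric.

Model families: partial least squares (PLS), random forest (RF), and support
vector regression (SVR), each optionally preceded by a PCA step fitted on the
training rows only (the scaler -> PCA -> regressor stack is frozen as one
transform).  The GA fitness loop evaluates tens of thousands of candidate
descriptor subsets, so PLS with a single response is also available through a
lightweight NIPALS implementation that produces the same predictions as
scikit-learn's ``PLSRegression`` but without estimator-construction overhead.

The cross-validated score is the arithmetic mean of the per-fold coefficients
of determination computed on each held-out fold; the pooled-prediction
variant is also reported but the per-fold mean is the authoritative figure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVR

from .data_io import DescriptorTable, SplitResult


class UndefinedMetricError(ValueError):
    """R-squared is undefined (constant actuals or too few points)."""


MODEL_FAMILIES = ("pls", "rf", "svr")


@dataclass
class ModelSpec:
    """A regressor choice with optional PCA step and hyperparameters.

    ``params`` holds family-specific settings: ``n_components`` for PLS,
    anything ``RandomForestRegressor``/``SVR`` accept for the others.  When
    ``pca_components`` is set the design matrix is min-max scaled, projected
    onto that many principal components, and only then passed to the
    regressor; all three steps are fitted on the training rows alone.
    """

    family: str = "pls"
    pca_components: int | None = None
    params: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; use one of {MODEL_FAMILIES}")
        if self.pca_components is not None and self.pca_components < 1:
            raise ValueError("pca_components must be >= 1")


@dataclass
class EvalReport:
    """Train / cross-validation / test R-squared for one fitted model."""

    tr_r2: float
    cv_r2: float
    te_r2: float | None = None
    fold_scores: list[float] = field(default_factory=list)
    pooled_cv_r2: float | None = None
    explained_variance_fraction: float | None = None

    def to_dict(self) -> dict:
        return {
            "tr_r2": self.tr_r2,
            "cv_r2": self.cv_r2,
            "te_r2": self.te_r2,
            "fold_scores": list(self.fold_scores),
            "pooled_cv_r2": self.pooled_cv_r2,
            "explained_variance_fraction": self.explained_variance_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(**d)


def r_squared(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    SS_tot is centered on the mean of the *actual* values.  Undefined when the
    actuals are constant or fewer than two points are supplied.
    """
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have the same length")
    if actual.size < 2:
        raise UndefinedMetricError("need at least 2 observations for R^2")
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined: actual values are constant")
    ss_res = float(np.sum((actual - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# fast single-response PLS (NIPALS); prediction-identical to PLSRegression
# ---------------------------------------------------------------------------

def pls1_coefficients(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[np.ndarray, float]:
    """Slope vector and intercept of a PLS1 fit on standardized data.

    Deflation follows NIPALS; columns with zero variance are tolerated (their
    weight is zero).  Components stop early if the residual weight vector
    collapses, mirroring the effective rank of the data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    n_components = int(min(n_components, p, n - 1))
    if n_components < 1:
        raise ValueError("need at least one PLS component")
    xm = X.mean(axis=0)
    xs = X.std(axis=0, ddof=1)
    xs = np.where(xs == 0, 1.0, xs)
    ym = y.mean()
    ys = y.std(ddof=1)
    ys = ys if ys > 0 else 1.0
    Xd = (X - xm) / xs
    yd = (y - ym) / ys

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    Q = np.empty(n_components)
    k = 0
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pa = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        Xd -= np.outer(t, pa)
        yd = yd - qa * t
        W[:, a], P[:, a], Q[a] = w, pa, qa
        k += 1
    if k == 0:
        return np.zeros(p), float(ym)
    W, P, Q = W[:, :k], P[:, :k], Q[:k]
    beta_std = W @ np.linalg.solve(P.T @ W, Q)
    coef = beta_std * ys / xs
    intercept = float(ym - xm @ coef)
    return coef, intercept


class FastPLS1(RegressorMixin, BaseEstimator):
    """Minimal PLS1 estimator with the sklearn fit/predict surface."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        self.coef_, self.intercept_ = pls1_coefficients(X, y, self.n_components)
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def _make_regressor(spec: ModelSpec, n_features: int, n_train: int, fast_pls: bool = False):
    if spec.family == "pls":
        ncomp = int(spec.params.get("n_components", 2))
        ncomp = max(1, min(ncomp, n_features, n_train - 1))
        if fast_pls:
            return FastPLS1(n_components=ncomp)
        return PLSRegression(n_components=ncomp, scale=True)
    if spec.family == "rf":
        params = {"n_estimators": 300, "random_state": spec.rng_seed}
        params.update(spec.params)
        return RandomForestRegressor(**params)
    if spec.family == "svr":
        params = {"kernel": "rbf", "C": 10.0, "gamma": "scale"}
        params.update(spec.params)
        return SVR(**params)
    raise ValueError(spec.family)


def build_pipeline(spec: ModelSpec, n_features: int, n_train: int, fast_pls: bool = False) -> Pipeline:
    """Assemble scaler [-> PCA] -> regressor for the given data shape."""
    steps = [("scale", MinMaxScaler())]
    if spec.pca_components is not None:
        ncomp = min(spec.pca_components, n_features, n_train)
        if spec.pca_components > min(n_features, n_train):
            raise ValueError(
                f"pca_components={spec.pca_components} exceeds data rank bound "
                f"min(n_features={n_features}, n_train={n_train})"
            )
        steps.append(("pca", PCA(n_components=ncomp, random_state=spec.rng_seed)))
    steps.append(("model", _make_regressor(spec, n_features, n_train, fast_pls=fast_pls)))
    return Pipeline(steps)


def fit_predict(
    spec: ModelSpec,
    train: DescriptorTable,
    apply_to: DescriptorTable,
    fast_pls: bool = False,
) -> tuple[np.ndarray, Pipeline]:
    """Fit the spec's pipeline on ``train`` and predict for ``apply_to``.

    Returns predictions in ``apply_to`` row order together with the fitted
    pipeline.  Deterministic given ``spec.rng_seed``.
    """
    if train.target is None:
        raise ValueError("training table has no target")
    if list(train.descriptor_names) != list(apply_to.descriptor_names):
        raise ValueError("descriptor sets of train and apply_to differ")
    pipe = build_pipeline(spec, train.n_descriptors, train.n_samples, fast_pls=fast_pls)
    pipe.fit(train.values, train.target)
    pred = np.asarray(pipe.predict(apply_to.values), dtype=float).ravel()
    return pred, pipe


def cross_validate(
    spec: ModelSpec,
    train: DescriptorTable,
    folds: int = 5,
    rng_seed: int = 0,
    fold_indices: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    fast_pls: bool = False,
) -> tuple[float, list[float], float]:
    """k-fold CV; returns (mean per-fold R^2, per-fold scores, pooled R^2).

    Folds come from a seeded shuffle unless explicit ``fold_indices`` are
    given.  The scaler and any PCA step are refitted inside each fold.  A fold
    whose held-out targets are constant makes the metric undefined and raises.
    """
    if train.target is None:
        raise ValueError("training table has no target")
    n = train.n_samples
    if folds > n:
        raise ValueError(f"folds={folds} exceeds n_train={n}")
    if fold_indices is None:
        kf = KFold(n_splits=folds, shuffle=True, random_state=rng_seed)
        fold_indices = list(kf.split(np.arange(n)))
    # fast path: PLS1 standardizes columns internally, so the min-max scaling
    # step is prediction-neutral and the pipeline machinery can be skipped
    direct_pls = fast_pls and spec.family == "pls" and spec.pca_components is None
    scores: list[float] = []
    pooled_pred = np.empty(n)
    for tr_idx, te_idx in fold_indices:
        if len(te_idx) < 2:
            raise UndefinedMetricError(
                "a CV fold holds out fewer than 2 points; per-fold R^2 is undefined "
                "(reduce the number of folds)"
            )
        if direct_pls:
            ncomp = int(spec.params.get("n_components", 2))
            ncomp = max(1, min(ncomp, train.n_descriptors, len(tr_idx) - 1))
            coef, icpt = pls1_coefficients(
                train.values[tr_idx], train.target[tr_idx], ncomp
            )
            pred = train.values[te_idx] @ coef + icpt
        else:
            pipe = build_pipeline(spec, train.n_descriptors, len(tr_idx), fast_pls=fast_pls)
            pipe.fit(train.values[tr_idx], train.target[tr_idx])
            pred = np.asarray(pipe.predict(train.values[te_idx]), dtype=float).ravel()
        scores.append(r_squared(train.target[te_idx], pred))
        pooled_pred[te_idx] = pred
    cv_r2 = float(np.mean(scores))
    pooled = r_squared(train.target, pooled_pred)
    return cv_r2, scores, pooled


def evaluate(
    spec: ModelSpec,
    split: SplitResult,
    data: DescriptorTable,
    folds: int = 5,
    rng_seed: int = 0,
) -> EvalReport:
    """Fit on the training partition; report train, CV and test R-squared.

    When a PCA step is used the cumulative explained-variance fraction of the
    retained components (on the training rows) is included.
    """
    train = data.subset_rows(split.train_indices)
    pred_tr, pipe = fit_predict(spec, train, train)
    tr_r2 = r_squared(train.target, pred_tr)
    cv_r2, fold_scores, pooled = cross_validate(spec, train, folds=folds, rng_seed=rng_seed)

    te_r2 = None
    if split.test_indices:
        test = data.subset_rows(split.test_indices)
        pred_te = np.asarray(pipe.predict(test.values), dtype=float).ravel()
        if test.target is None:
            warnings.warn("test rows have no target; te_r2 omitted")
        else:
            te_r2 = r_squared(test.target, pred_te)
    else:
        warnings.warn("empty test set; te_r2 omitted")

    evf = None
    if spec.pca_components is not None:
        evf = float(np.sum(pipe.named_steps["pca"].explained_variance_ratio_))
    return EvalReport(
        tr_r2=tr_r2,
        cv_r2=cv_r2,
        te_r2=te_r2,
        fold_scores=fold_scores,
        pooled_cv_r2=pooled,
        explained_variance_fraction=evf,
    )
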