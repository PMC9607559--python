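"""Pearson relevance/redundancy pre-filter and early-stopping grid search.

This is the deterministic alternative to the GA selector: descriptors are
first screened by Pearson correlation (keep those sufficiently correlated
with the target, drop those too correlated with an already-kept descriptor),
then the screened list's prefixes are treated as a subset-size hyperparameter
and crossed with each model family's hyperparameter grid under repeated
k-fold cross-validation.  Growth over the subset size stops early once the
best achievable score stops improving, which guards against overfitting the
tiny sample sizes typical of this domain.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import RepeatedKFold

from .data_io import DescriptorTable
from .modeling import ModelSpec, build_pipeline, r_squared


@dataclass
class ScreenConfig:
    """Thresholds and CV settings for the correlation screen + grid search.

    ``relevance_min``: minimum |r| between a descriptor and the target;
    ``redundancy_max``: maximum |r| allowed between two kept descriptors;
    scores are means over ``n_repeats`` repetitions of ``cv_folds``-fold CV;
    ``early_stop_tol`` is the relative best-score improvement below which the
    subset-size loop halts.
    """

    relevance_min: float = 0.1
    redundancy_max: float = 0.5
    cv_folds: int = 5
    n_repeats: int = 10
    early_stop_tol: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("relevance_min", "redundancy_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class GridResult:
    subset_size: int
    subset_names: list[str]
    params: dict
    cv_score: float
    table: list[dict] = field(default_factory=list)
    stopped_early: bool = False


def pearson_prefilter(data: DescriptorTable, config: ScreenConfig) -> list[str]:
    """Greedy relevance/redundancy screen; returns names in acceptance order.

    Candidates with |corr(descriptor, target)| >= ``relevance_min`` are
    visited in descending relevance (ties by name, ascending) and kept iff
    their absolute correlation with every already-kept descriptor does not
    exceed ``redundancy_max``.
    """
    if data.target is None:
        raise ValueError("prefilter needs a table with targets")
    X, y = data.values, data.target
    stds = X.std(axis=0)
    if np.any(stds == 0):
        raise ValueError("constant columns present; run remove_constant_columns first")

    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        raise ValueError("target is constant; correlations undefined")
    Xc = X - X.mean(axis=0)
    xnorm = np.linalg.norm(Xc, axis=0)
    rel = np.abs(Xc.T @ yc) / (xnorm * ynorm)

    cand = [j for j in range(data.n_descriptors) if rel[j] >= config.relevance_min]
    if not cand:
        warnings.warn("no descriptor passes the relevance threshold")
        return []
    cand.sort(key=lambda j: (-rel[j], data.descriptor_names[j]))

    kept: list[int] = []
    Xn = Xc / xnorm
    for j in cand:
        if all(abs(float(Xn[:, j] @ Xn[:, k])) <= config.redundancy_max for k in kept):
            kept.append(j)
    return [data.descriptor_names[j] for j in kept]


DEFAULT_GRIDS: dict[str, list[dict]] = {
    "svr": [
        {"C": c, "gamma": g}
        for c in (0.1, 1.0, 10.0, 100.0)
        for g in (0.01, 0.1, 1.0)
    ],
    "rf": [
        {"n_estimators": n, "max_depth": d}
        for n in (100, 300)
        for d in (None, 3, 5)
    ],
    # PLS grid depends on the subset size; built per k in grid_search
}


def _param_grid(family: str, k: int, n_train: int) -> list[dict]:
    if family == "pls":
        return [{"n_components": c} for c in range(1, min(k, n_train - 1) + 1)]
    if family in DEFAULT_GRIDS:
        return DEFAULT_GRIDS[family]
    raise ValueError(f"no hyperparameter grid for model family {family!r}")


def repeated_cv_score(
    data: DescriptorTable,
    names: list[str],
    spec: ModelSpec,
    config: ScreenConfig,
) -> float:
    """Mean per-fold R^2 over n_repeats x cv_folds repeated cross-validation."""
    sub = data.subset_columns(names)
    rkf = RepeatedKFold(
        n_splits=config.cv_folds, n_repeats=config.n_repeats,
        random_state=config.rng_seed,
    )
    scores = []
    for tr, te in rkf.split(sub.values):
        pipe = build_pipeline(spec, sub.n_descriptors, len(tr))
        pipe.fit(sub.values[tr], sub.target[tr])
        pred = np.asarray(pipe.predict(sub.values[te]), dtype=float).ravel()
        scores.append(r_squared(sub.target[te], pred))
    return float(np.mean(scores))


def grid_search(
    data: DescriptorTable,
    filtered: list[str],
    family: str,
    config: ScreenConfig,
) -> GridResult:
    """Search subset-size prefixes x hyperparameters; stop when gains vanish.

    For k = 1..len(filtered) the top-k prefix of the screened list is crossed
    with the family's hyperparameter grid; each cell is scored by repeated-CV
    mean R^2.  After k >= 2, if the relative improvement of the running best
    score over the previous best falls below ``early_stop_tol`` the loop
    halts (patience 1).  With tol = 0 the search is exhaustive over k.
    """
    if not filtered:
        raise ValueError("filtered descriptor list is empty")
    if family not in ("pls", "rf", "svr"):
        raise ValueError(f"unknown model family {family!r}")

    n_train = data.n_samples
    best: GridResult | None = None
    table: list[dict] = []
    prev_best_score: float | None = None
    stopped = False

    for k in range(1, len(filtered) + 1):
        names = filtered[:k]
        for params in _param_grid(family, k, n_train):
            spec = ModelSpec(family=family, params=dict(params), rng_seed=config.rng_seed)
            score = repeated_cv_score(data, names, spec, config)
            table.append({"size": k, "params": dict(params), "cv_score": score})
            if best is None or score > best.cv_score:
                best = GridResult(
                    subset_size=k, subset_names=list(names),
                    params=dict(params), cv_score=score,
                )
        if prev_best_score is not None:
            denom = max(abs(prev_best_score), 1e-12)
            improvement = (best.cv_score - prev_best_score) / denom
            if improvement < config.early_stop_tol:
                stopped = k < len(filtered)
                break
        prev_best_score = best.cv_score

    best.table = table
    best.stopped_early = stopped
    return best
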