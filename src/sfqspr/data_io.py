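"""Descriptor-matrix I/O, cleaning, min-max scaling and Kennard-Stone division.

The central container is :class:`DescriptorTable`: a molecules x descriptors
numeric matrix with an optional aligned target vector (here, the plasticizer
substitution factor).  Everything downstream -- the genetic-algorithm
selectors, the correlation screen and the regression models -- consumes this
container.

CSV conventions: comma-separated UTF-8 with a header row; the first column is
the molecule identifier.  Missing cells are an error, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


class AlignmentError(ValueError):
    """Molecule ids of the matrix and the target table do not match."""


class ParseError(ValueError):
    """A cell could not be interpreted as a number."""


class ConstantColumnError(ValueError):
    """An operation met a zero-variance descriptor it cannot handle."""


@dataclass
class DescriptorTable:
    """Molecules x named numeric descriptors, plus an optional target vector.

    Invariants enforced at construction: unique descriptor names, no missing
    values, at least two rows, and the target (when present) aligned to
    ``molecule_ids`` by position.
    """

    molecule_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    target: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 molecules, got {n}")
        if len(self.molecule_ids) != n:
            raise ValueError("molecule_ids length does not match matrix rows")
        if len(self.descriptor_names) != d:
            raise ValueError("descriptor_names length does not match matrix columns")
        if len(set(self.descriptor_names)) != d:
            raise ValueError("descriptor names must be unique")
        if not np.isfinite(self.values).all():
            raise ParseError("matrix contains missing or non-finite values")
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)
            if self.target.shape != (n,):
                raise ValueError("target length does not match number of molecules")
            if not np.isfinite(self.target).all():
                raise ParseError("target contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, rows: Sequence[int]) -> "DescriptorTable":
        rows = list(rows)
        return DescriptorTable(
            molecule_ids=[self.molecule_ids[i] for i in rows],
            descriptor_names=list(self.descriptor_names),
            values=self.values[rows],
            target=None if self.target is None else self.target[rows],
        )

    def subset_columns(self, names: Sequence[str]) -> "DescriptorTable":
        idx = [self.descriptor_names.index(nm) for nm in names]
        return DescriptorTable(
            molecule_ids=list(self.molecule_ids),
            descriptor_names=list(names),
            values=self.values[:, idx],
            target=None if self.target is None else self.target.copy(),
        )

    def column_indices(self, names: Sequence[str]) -> np.ndarray:
        pos = {nm: i for i, nm in enumerate(self.descriptor_names)}
        return np.array([pos[nm] for nm in names], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.molecule_ids, columns=self.descriptor_names
        )
        df.index.name = "molecule_id"
        return df


@dataclass
class SplitResult:
    """Disjoint train/test row indices covering all molecules."""

    train_indices: list[int]
    test_indices: list[int]
    method: str = "kennard_stone"

    def __post_init__(self) -> None:
        tr, te = set(self.train_indices), set(self.test_indices)
        if tr & te:
            raise ValueError("train and test indices overlap")
        if len(self.train_indices) < 2:
            raise ValueError("training partition needs at least 2 rows")

    def validate_cover(self, n: int) -> None:
        if set(self.train_indices) | set(self.test_indices) != set(range(n)):
            raise ValueError("split does not cover all rows exactly once")


@dataclass
class ScalerState:
    """Per-descriptor min/max learned on a fit partition."""

    descriptor_names: list[str]
    minima: np.ndarray
    maxima: np.ndarray
    clip: bool = False

    def __post_init__(self) -> None:
        if np.any(self.maxima < self.minima):
            raise ValueError("per-descriptor max must be >= min")


def load_table(matrix_path: str | Path, target_path: str | Path | None = None) -> DescriptorTable:
    """Read a descriptor matrix CSV and optionally attach a target table.

    The matrix row order is preserved.  Every molecule id in the matrix must
    appear in the target file; otherwise an :class:`AlignmentError` names the
    missing ids.  Non-numeric cells raise :class:`ParseError` naming the
    offending row and column.
    """
    df = pd.read_csv(matrix_path, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            row = bad[0] if len(bad) else "?"
            raise ParseError(
                f"non-numeric cell at row {row!r}, column {col!r} in {matrix_path}"
            ) from None
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise ParseError(
            f"missing cell at row {df.index[i]!r}, column {df.columns[j]!r} in {matrix_path}"
        )

    target = None
    if target_path is not None:
        tdf = pd.read_csv(target_path, index_col=0)
        tdf.index = tdf.index.astype(str)
        if tdf.shape[1] != 1:
            raise ParseError(f"target file {target_path} must have exactly one value column")
        tser = pd.to_numeric(tdf.iloc[:, 0], errors="coerce")
        if tser.isna().any():
            bad = tdf.index[tser.isna()][0]
            raise ParseError(f"non-numeric target for molecule {bad!r} in {target_path}")
        missing = [mid for mid in df.index if mid not in tser.index]
        if missing:
            raise AlignmentError(
                f"molecules without a target value: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        target = tser.reindex(df.index).to_numpy(dtype=float)

    return DescriptorTable(
        molecule_ids=list(df.index),
        descriptor_names=list(df.columns),
        values=values,
        target=target,
    )


def remove_constant_columns(table: DescriptorTable) -> tuple[DescriptorTable, list[str]]:
    """Drop zero-variance descriptors; return survivors and removed names.

    Survivor order is preserved.  Raises :class:`ConstantColumnError` if every
    column is constant (nothing left to model with).
    """
    keep_mask = np.array(
        [np.unique(table.values[:, j]).size > 1 for j in range(table.n_descriptors)]
    )
    removed = [nm for nm, k in zip(table.descriptor_names, keep_mask) if not k]
    if not keep_mask.any():
        raise ConstantColumnError("all descriptor columns are constant")
    if not removed:
        return table, []
    kept_names = [nm for nm, k in zip(table.descriptor_names, keep_mask) if k]
    out = DescriptorTable(
        molecule_ids=list(table.molecule_ids),
        descriptor_names=kept_names,
        values=table.values[:, keep_mask],
        target=None if table.target is None else table.target.copy(),
    )
    return out, removed


def fit_minmax(table: DescriptorTable, rows: Sequence[int] | None = None, clip: bool = False) -> ScalerState:
    """Learn per-descriptor min/max on ``rows`` (default: all rows).

    Columns constant on the fit rows raise :class:`ConstantColumnError`
    pointing the user at :func:`remove_constant_columns`.
    """
    rows = list(range(table.n_samples)) if rows is None else list(rows)
    if not rows:
        raise ValueError("fit rows must be nonempty")
    sub = table.values[rows]
    minima = sub.min(axis=0)
    maxima = sub.max(axis=0)
    flat = np.flatnonzero(maxima == minima)
    if flat.size:
        names = [table.descriptor_names[j] for j in flat[:5]]
        raise ConstantColumnError(
            f"descriptors constant on the fit rows: {names}; run remove_constant_columns first"
        )
    return ScalerState(
        descriptor_names=list(table.descriptor_names),
        minima=minima,
        maxima=maxima,
        clip=clip,
    )


def apply_minmax(state: ScalerState, table: DescriptorTable) -> DescriptorTable:
    """Map descriptors through (x - min) / (max - min).

    Fit rows land in [0, 1]; out-of-sample rows may exceed that range unless
    the scaler was built with ``clip=True``.
    """
    if list(table.descriptor_names) != list(state.descriptor_names):
        raise ValueError("scaler was fitted on a different descriptor set")
    scaled = (table.values - state.minima) / (state.maxima - state.minima)
    if state.clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    return replace(table, values=scaled,
                   molecule_ids=list(table.molecule_ids),
                   descriptor_names=list(table.descriptor_names),
                   target=None if table.target is None else table.target.copy())


def kennard_stone_split(table: DescriptorTable, n_train: int, scale: bool = True) -> SplitResult:
    """Deterministic max-min-distance division into train and test rows.

    The first two picks are the globally most distant pair of molecules; every
    subsequent pick maximizes its minimum Euclidean distance to the rows
    already picked.  Distances are computed on min-max-scaled descriptors so
    the division is invariant to descriptor units.  Ties are broken toward the
    lowest row index, which makes the split fully reproducible.
    """
    n = table.n_samples
    if not 2 <= n_train <= n:
        raise ValueError(f"n_train must be in [2, {n}], got {n_train}")
    X = table.values
    if scale:
        rng_span = X.max(axis=0) - X.min(axis=0)
        safe = np.where(rng_span == 0, 1.0, rng_span)
        X = (X - X.min(axis=0)) / safe
    dist = cdist(X, X)

    # most distant pair; lexicographically smallest (i, j) on ties
    iu = np.triu_indices(n, k=1)
    flat_best = np.argmax(dist[iu])
    best_d = dist[iu][flat_best]
    candidates = [
        (i, j) for i, j in zip(*iu) if dist[i, j] == best_d
    ]
    i0, j0 = min(candidates)
    selected = [int(i0), int(j0)]
    remaining = [i for i in range(n) if i not in selected]

    min_dist = np.minimum(dist[i0], dist[j0])
    while len(selected) < n_train:
        cand = np.array(remaining)
        dvals = min_dist[cand]
        pick = int(cand[np.argmax(dvals)])  # argmax returns first max: lowest index wins
        selected.append(pick)
        remaining.remove(pick)
        min_dist = np.minimum(min_dist, dist[pick])

    split = SplitResult(
        train_indices=selected,
        test_indices=sorted(remaining),
        method="kennard_stone",
    )
    split.validate_cover(n)
    return split


def save_split(split: SplitResult, table: DescriptorTable, path: str | Path) -> None:
    """Serialize a split as a two-column CSV (molecule id, partition)."""
    part = {i: "train" for i in split.train_indices}
    part.update({i: "test" for i in split.test_indices})
    rows = [(table.molecule_ids[i], part[i]) for i in range(table.n_samples)]
    pd.DataFrame(rows, columns=["molecule_id", "partition"]).to_csv(path, index=False)


def load_split(path: str | Path, table: DescriptorTable) -> SplitResult:
    df = pd.read_csv(path, dtype=str)
    pos = {mid: i for i, mid in enumerate(table.molecule_ids)}
    train, test = [], []
    for mid, p in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if mid not in pos:
            raise AlignmentError(f"split references unknown molecule {mid!r}")
        (train if p == "train" else test).append(pos[mid])
    split = SplitResult(train_indices=train, test_indices=test, method="manual")
    split.validate_cover(table.n_samples)
    return split
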