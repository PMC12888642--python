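"""Per-site random-forest training with nested hyper-parameter tuning.

Each site trains its own forest; the positive-class probability of a
forest is the mean over its trees of the positive-class relative frequency
in the terminal node the sample falls into.  Hyper-parameters (ntree, the
number of trees, and mtry, the number of candidate features per split) are
tuned by grid search under repeated stratified inner cross-validation with
accuracy at the 0.5 cutoff as the criterion; tuning only ever sees the
training partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .cohort import SiteCohort


@dataclass(frozen=True)
class HyperParameterGrid:
    ntree_values: tuple[int, ...]
    mtry_values: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.ntree_values or not self.mtry_values:
            raise ValueError("grid must be nonempty")
        if min(self.ntree_values) < 1 or min(self.mtry_values) < 1:
            raise ValueError("grid values must be >= 1")

    @classmethod
    def default(cls, d: int) -> "HyperParameterGrid":
        """Desk-scale grid: ntree {100,300,500} x mtry sqrt(d)+-2."""
        center = max(1, int(np.sqrt(d)))
        mtry = tuple(sorted({max(1, min(d, center + k)) for k in range(-2, 3)}))
        return cls((100, 300, 500), mtry)

    @classmethod
    def full(cls, d: int = 30) -> "HyperParameterGrid":
        """The cluster-scale reference grid: ntree 100..1000, mtry 1..30."""
        return cls(tuple(range(100, 1001, 100)), tuple(range(1, min(d, 30) + 1)))


@dataclass(frozen=True)
class InnerCVSpec:
    repeats: int = 5
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1 or self.folds < 2:
            raise ValueError("need repeats >= 1 and folds >= 2")


@dataclass
class LocalForest:
    """A trained per-site forest.

    ``predict_probability`` returns, for each sample, the arithmetic mean
    over the forest's trees of the positive-class relative frequency in the
    tree's terminal node (exactly what sklearn's predict_proba computes).
    """

    site_id: str
    ntree: int
    mtry: int
    seed: int
    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    training_fold: str = ""

    @property
    def trees(self):
        return self.estimator.estimators_

    def _positive_column(self, proba: np.ndarray, classes: np.ndarray) -> np.ndarray:
        idx = np.flatnonzero(classes == 1)
        if idx.size:
            return proba[:, idx[0]]
        return np.zeros(proba.shape[0])  # forest never saw a positive

    def predict_probability(self, features) -> np.ndarray:
        X = _as_matrix(features, self.feature_names)
        proba = self.estimator.predict_proba(X)
        return self._positive_column(proba, self.estimator.classes_)

    def per_tree_probabilities(self, features) -> np.ndarray:
        """(ntree, n_samples) matrix of terminal-node positive frequencies."""
        X = _as_matrix(features, self.feature_names)
        return np.stack(
            [
                self._positive_column(tree.predict_proba(X), self.estimator.classes_)
                for tree in self.trees
            ]
        )


def _as_matrix(features, names: Sequence[str]) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in names if c not in features.columns]
        if missing:
            raise ValueError(f"features missing columns {missing}")
        return features.loc[:, list(names)].to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(names):
        raise ValueError("feature matrix does not conform to the training schema")
    return X


def train_local_forest(
    train: SiteCohort, ntree: int, mtry: int, seed: int
) -> LocalForest:
    """Fit a forest of exactly ``ntree`` CART trees (Gini, bootstrap, no
    depth limit) with ``mtry`` candidate features per split."""
    if train.n == 0:
        raise ValueError("empty training set")
    d = train.features.shape[1]
    if mtry > d:
        warnings.warn(f"mtry {mtry} > d {d}; clipping", stacklevel=2)
        mtry = d
    classes = np.unique(train.labels)
    if classes.size < 2:
        warnings.warn(
            f"site {train.site_id}: single-class training labels; "
            "predictions will be constant",
            stacklevel=2,
        )
    est = RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry,
        criterion="gini",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(train.features.to_numpy(dtype=float), train.labels)
    return LocalForest(
        site_id=train.site_id,
        ntree=ntree,
        mtry=mtry,
        seed=seed,
        estimator=est,
        feature_names=tuple(str(c) for c in train.features.columns),
    )


def predict_probability(model: LocalForest, features) -> np.ndarray:
    return model.predict_probability(features)


def tune_hyperparameters(
    train: SiteCohort, grid: HyperParameterGrid, spec: InnerCVSpec
) -> tuple[int, int]:
    """Grid cell with the highest mean inner-CV accuracy (0.5 cutoff).

    Ties break toward the earliest grid cell (smaller ntree, then smaller
    mtry).  A one-cell grid returns immediately without any inner CV.
    """
    d = train.features.shape[1]
    mtry_values = []
    for m in grid.mtry_values:
        if m > d:
            warnings.warn(f"mtry {m} exceeds d={d}; clipping", stacklevel=2)
            m = d
        if m not in mtry_values:
            mtry_values.append(m)

    cells = [(nt, m) for nt in grid.ntree_values for m in mtry_values]
    if len(cells) == 1:
        return cells[0]

    if np.unique(train.labels).size < 2:
        raise ValueError("cannot tune on single-class training data")

    X = train.features.to_numpy(dtype=float)
    y = train.labels
    cv = RepeatedStratifiedKFold(
        n_splits=spec.folds, n_repeats=spec.repeats, random_state=spec.seed
    )
    splits = list(cv.split(X, y))

    best, best_acc = cells[0], -np.inf
    for nt, m in cells:
        accs = []
        for tr_idx, va_idx in splits:
            est = RandomForestClassifier(
                n_estimators=nt,
                max_features=m,
                criterion="gini",
                bootstrap=True,
                random_state=spec.seed,
                n_jobs=1,
            )
            est.fit(X[tr_idx], y[tr_idx])
            proba = est.predict_proba(X[va_idx])
            pos = np.flatnonzero(est.classes_ == 1)
            p = proba[:, pos[0]] if pos.size else np.zeros(len(va_idx))
            accs.append(np.mean((p >= 0.5).astype(int) == y[va_idx]))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc:
            best, best_acc = (nt, m), mean_acc
    return best
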