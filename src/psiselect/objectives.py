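"""Four-objective evaluation of a candidate feature subset.

A subset (binary mask over the columns of a labeled feature table) is
scored by four quantities, all minimized jointly:

  F1  10-fold (or leave-one-out) cross-validated error of an RBF-kernel SVM
  F2  the same for Gaussian naive Bayes
  F3  the same for linear discriminant analysis
  F4  a sigmoid-squashed class-separability measure built from Euclidean
      distances on the masked columns:

        D_b = mean_i  min_{j : class(j) != class(i)}  dis(i, j)
        D_w = mean_i  max_{j != i : class(j) = class(i)}  dis(i, j)
        F4  = 1 / (1 + exp(-(D_w - D_b)))

      so compact classes far apart (D_b >> D_w) drive F4 toward 0.

The three classifiers share one stratified fold assignment per evaluation,
features are z-scored with training-fold statistics only, and objective
vectors are memoized by mask since a subset search revisits masks often.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

__all__ = [
    "Dataset",
    "ObjectiveVector",
    "SubsetEvaluator",
    "cv_error",
    "distance_objective",
    "evaluate_subset",
]

#: Objective vector returned for an empty mask: worst possible everywhere.
EMPTY_MASK_PENALTY = (1.0, 1.0, 1.0, 1.0)

CLASSIFIERS = ("svm", "nb", "da")


@dataclass
class Dataset:
    """Labeled feature table: samples x features with binary group labels."""

    table: np.ndarray
    labels: np.ndarray
    feature_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.table.ndim != 2:
            raise ValueError("table must be samples x features")
        if len(self.labels) != self.table.shape[0]:
            raise ValueError("labels length must match sample count")
        if not np.isfinite(self.table).all():
            raise ValueError("table contains non-finite values")
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) != 2:
            raise ValueError("exactly two classes are required")
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples")
        if self.feature_names is None:
            self.feature_names = [f"f{i}" for i in range(self.table.shape[1])]
        elif len(self.feature_names) != self.table.shape[1]:
            raise ValueError("feature_names length must match column count")

    @property
    def n_samples(self) -> int:
        return self.table.shape[0]

    @property
    def n_features(self) -> int:
        return self.table.shape[1]

    def binary_labels(self) -> np.ndarray:
        classes = np.unique(self.labels)
        return (self.labels == classes[1]).astype(int)


@dataclass(frozen=True)
class ObjectiveVector:
    """(F1, F2, F3, F4), all in [0, 1], minimized jointly."""

    f1: float
    f2: float
    f3: float
    f4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3, self.f4])

    @property
    def mean_error(self) -> float:
        """Mean of the three classifier errors (the reporting headline)."""
        return (self.f1 + self.f2 + self.f3) / 3.0


def _make_classifier(name: str):
    if name == "svm":
        # gamma="scale" is 1 / (n_features * X.var()), i.e. ~1/D after z-scoring
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if name == "nb":
        return GaussianNB()
    if name == "da":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown classifier {name!r}")


def _fold_indices(y: np.ndarray, scheme: str, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    n = len(y)
    if scheme == "kfold10":
        # 10 folds at the design scale; capped by the smallest class so tiny
        # tables still cross-validate (stratification needs >= 1 per fold)
        n_splits = int(min(10, np.bincount(y).min()))
        if n_splits < 2:
            raise ValueError("need at least 2 samples per class for k-fold CV")
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return list(skf.split(np.zeros(n), y))
    if scheme == "loo":
        idx = np.arange(n)
        return [(np.delete(idx, i), idx[i : i + 1]) for i in range(n)]
    raise ValueError(f"unknown scheme {scheme!r}; use 'kfold10' or 'loo'")


def _fold_errors(
    x: np.ndarray, y: np.ndarray, folds, names: Sequence[str]
) -> dict[str, float]:
    """Per-classifier mean misclassification over shared folds, with
    training-fold z-scoring."""
    errs = {name: [] for name in names}
    for train, test in folds:
        mu = x[train].mean(axis=0)
        sd = x[train].std(axis=0)
        sd[sd == 0.0] = 1.0
        xtr = (x[train] - mu) / sd
        xte = (x[test] - mu) / sd
        for name in names:
            clf = _make_classifier(name)
            clf.fit(xtr, y[train])
            errs[name].append(float(np.mean(clf.predict(xte) != y[test])))
    return {name: float(np.mean(v)) for name, v in errs.items()}


def cv_error(
    ds: Dataset,
    mask: np.ndarray,
    classifier: str = "svm",
    scheme: str = "kfold10",
    seed: int = 0,
) -> float:
    """Cross-validated misclassification rate of one classifier on the
    masked columns."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (ds.n_features,):
        raise ValueError("mask length must match feature count")
    if not mask.any():
        raise ValueError("mask selects no features")
    y = ds.binary_labels()
    folds = _fold_indices(y, scheme, seed)
    return _fold_errors(ds.table[:, mask], y, folds, [classifier])[classifier]


def distance_objective(ds: Dataset, mask: np.ndarray) -> float:
    """F4 on the masked columns.

    A singleton class contributes 0 to its D_w term (no same-class peer).
    Always strictly inside (0, 1).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no features")
    x = ds.table[:, mask]
    y = ds.binary_labels()
    d = squareform(pdist(x, metric="euclidean"))
    n = len(y)
    same = y[:, None] == y[None, :]
    np.fill_diagonal(same, False)
    diff = y[:, None] != y[None, :]
    d_b = np.where(diff, d, np.inf).min(axis=1).mean()
    with_peer = same.any(axis=1)
    d_w_terms = np.zeros(n)
    d_w_terms[with_peer] = np.where(same, d, -np.inf)[with_peer].max(axis=1)
    d_w = d_w_terms.mean()
    return float(1.0 / (1.0 + np.exp(-(d_w - d_b))))


def evaluate_subset(
    ds: Dataset,
    mask: np.ndarray,
    scheme: str = "kfold10",
    seed: int = 0,
) -> ObjectiveVector:
    """(F1, F2, F3, F4) for one mask, sharing a single fold assignment
    across the three classifiers.  The empty mask gets the penalty vector
    (1, 1, 1, 1)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return ObjectiveVector(*EMPTY_MASK_PENALTY)
    y = ds.binary_labels()
    folds = _fold_indices(y, scheme, seed)
    errs = _fold_errors(ds.table[:, mask], y, folds, CLASSIFIERS)
    return ObjectiveVector(
        errs["svm"], errs["nb"], errs["da"], distance_objective(ds, mask)
    )


@dataclass
class SubsetEvaluator:
    """Memoizing objective function over masks, with the evaluation log the
    optimizer needs (distinct masks visited, cache hits)."""

    ds: Dataset
    scheme: str = "kfold10"
    seed: int = 0
    _cache: dict[bytes, ObjectiveVector] = field(default_factory=dict, repr=False)
    n_calls: int = 0
    n_hits: int = 0

    def __call__(self, mask: np.ndarray) -> ObjectiveVector:
        mask = np.asarray(mask, dtype=bool)
        key = np.packbits(mask).tobytes()
        self.n_calls += 1
        hit = self._cache.get(key)
        if hit is not None:
            self.n_hits += 1
            return hit
        vec = evaluate_subset(self.ds, mask, self.scheme, self.seed)
        self._cache[key] = vec
        return vec

    @property
    def n_distinct_masks(self) -> int:
        """Count of distinct feature combinations evaluated so far."""
        return len(self._cache)
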