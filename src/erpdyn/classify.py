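"""Group classification from projection-difference features: linear SVM,
repeated stratified cross-validation, and a label-shuffle chance baseline."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import InvalidArgumentError


@dataclass
class CVResult:
    accuracies: np.ndarray              # per-repeat mean fold accuracy
    shuffled_accuracies: Optional[np.ndarray]
    folds: int
    repeats: int
    seed: int
    p_value: Optional[float] = None     # rank-sum real vs shuffled

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_shuffled_accuracy(self) -> Optional[float]:
        if self.shuffled_accuracies is None:
            return None
        return float(np.mean(self.shuffled_accuracies))


def build_features(
    projection_differences: Mapping[str, np.ndarray],
    window_average: bool = False,
    n_windows: int = 6,
) -> Tuple[List[str], np.ndarray]:
    """Flatten per-subject K x T projection-difference arrays into a feature
    matrix with deterministic (sorted-subject, row-major) ordering.

    ``window_average=True`` first averages T into ``n_windows`` equal blocks,
    giving K x n_windows features per subject.
    """
    if not projection_differences:
        raise InvalidArgumentError("no subjects")
    subjects = sorted(projection_differences.keys())
    shape = np.asarray(projection_differences[subjects[0]]).shape
    rows = []
    for s in subjects:
        arr = np.asarray(projection_differences[s], dtype=float)
        if arr.shape != shape:
            raise InvalidArgumentError(f"shape mismatch for subject {s}")
        if window_average:
            K, T = arr.shape
            if T % n_windows != 0:
                raise InvalidArgumentError(
                    f"{T} samples not divisible into {n_windows} windows"
                )
            arr = arr.reshape(K, n_windows, T // n_windows).mean(axis=2)
        rows.append(arr.ravel())
    return subjects, np.vstack(rows)


def _check_cv_inputs(x: np.ndarray, y: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InvalidArgumentError("need at least 2 classes")
    if counts.min() < folds:
        raise InvalidArgumentError(
            f"smallest class has {counts.min()} subjects < {folds} folds"
        )
    if len(x) != len(y):
        raise InvalidArgumentError("feature/label length mismatch")


def _one_repeat(x, y, folds, rs, C) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
    accs = []
    for train, test in skf.split(x, y):
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
        clf.fit(x[train], y[train])
        accs.append(float(np.mean(clf.predict(x[test]) == y[test])))
    return float(np.mean(accs))


def cross_validate(
    features: np.ndarray,
    labels: Sequence,
    folds: int = 10,
    repeats: int = 500,
    seed: int = 0,
    C: float = 1.0,
) -> CVResult:
    """Repeated stratified k-fold CV of a linear SVM.

    Per repeat: a fresh stratified split, per-feature standardisation fit on
    training folds only, accuracy averaged over held-out folds.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _check_cv_inputs(x, y, folds)
    rng = np.random.default_rng(seed)
    accs = np.array([
        _one_repeat(x, y, folds, int(rng.integers(2**31 - 1)), C)
        for _ in range(repeats)
    ])
    return CVResult(accuracies=accs, shuffled_accuracies=None,
                    folds=folds, repeats=repeats, seed=seed)


def shuffled_baseline(
    features: np.ndarray,
    labels: Sequence,
    folds: int = 10,
    repeats: int = 500,
    seed: int = 0,
    C: float = 1.0,
) -> np.ndarray:
    """Per-repeat CV accuracies with labels freshly permuted each repeat."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _check_cv_inputs(x, y, folds)
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(repeats):
        y_perm = rng.permutation(y)
        accs.append(_one_repeat(x, y_perm, folds, int(rng.integers(2**31 - 1)), C))
    return np.asarray(accs)


def classify_with_null(
    features: np.ndarray,
    labels: Sequence,
    folds: int = 10,
    repeats: int = 500,
    seed: int = 0,
    C: float = 1.0,
) -> CVResult:
    """Real repeated CV plus shuffled-label baseline, compared by a two-sided
    rank-sum test."""
    real = cross_validate(features, labels, folds, repeats, seed, C)
    shuffled = shuffled_baseline(features, labels, folds, repeats, seed + 1, C)
    stat, p = sps.ranksums(real.accuracies, shuffled)
    return CVResult(accuracies=real.accuracies, shuffled_accuracies=shuffled,
                    folds=folds, repeats=repeats, seed=seed, p_value=float(p))
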