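"""Classifier bank, iterative majority voting, and greedy outcome fusion.

Each of the four selected feature matrices is classified with kNN
(k=10, Euclidean, squared-inverse distance weights) and SVM (third-degree
polynomial kernel, box constraint 1, one-vs-all), both under stratified
10-fold cross-validation, giving 8 classifier-based outcomes.  Iterative
majority voting (IMV) then sorts the 8 outcomes by accuracy and, for
i = 3..8, takes the per-sample mode over the top-i outcomes, adding 6
voted outcomes.  A greedy step finally picks the single outcome — of the
14 — with maximal cross-validated accuracy; the whole bank is therefore
self-organizing.  Reported metrics: accuracy, macro F1, geometric mean
of per-class recalls, and the confusion matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _confusion_matrix
from sklearn.metrics import f1_score as _f1_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "Outcome",
    "FusionResult",
    "MetricsReport",
    "make_knn",
    "make_svm",
    "knn_outcome",
    "svm_outcome",
    "imv",
    "greedy_final",
    "compute_metrics",
    "make_folds",
]

KNN_NEIGHBORS = 10
SVM_DEGREE = 3
SVM_C = 1.0
IMV_RANGE = (3, 8)


@dataclass
class Outcome:
    """One per-sample prediction vector with its cross-validated accuracy."""

    predictions: np.ndarray  # (D,) integer class labels
    accuracy: float  # percent in [0, 100]
    source: tuple  # (ranker, classifier) or ("imv", i)
    kind: str  # "classifier" | "voted"

    def __post_init__(self):
        if self.kind not in ("classifier", "voted"):
            raise ValueError("kind must be 'classifier' or 'voted'")


@dataclass
class MetricsReport:
    """Accuracy, macro F1, geometric mean of recalls (all %), confusion."""

    accuracy: float
    f1: float
    geometric_mean: float
    confusion: np.ndarray  # (K, K) counts; rows true, columns predicted


@dataclass
class FusionResult:
    """All outcomes, the accuracy ordering, and the greedy winner."""

    outcomes: list[Outcome]
    sorted_order: np.ndarray  # outcome indices by descending accuracy
    winner_index: int
    final_predictions: np.ndarray
    metrics: MetricsReport | None = None

    @property
    def winner(self) -> Outcome:
        return self.outcomes[self.winner_index]


def _squared_inverse_weights(dist: np.ndarray) -> np.ndarray:
    """1/d^2 neighbor weights; an exact match (d=0) dominates its row."""
    with np.errstate(divide="ignore"):
        w = 1.0 / (dist**2)
    exact = np.isinf(w)
    rows = exact.any(axis=1)
    if rows.any():
        w[rows] = exact[rows].astype(float)
    return w


def make_knn(max_train_size: int | None = None) -> KNeighborsClassifier:
    """The pipeline's kNN: k=10, Euclidean, squared-inverse weighting."""
    k = KNN_NEIGHBORS
    if max_train_size is not None and max_train_size < k:
        logger.warning("kNN neighbors lowered from %d to %d (small training fold)",
                       k, max_train_size)
        k = max_train_size
    return KNeighborsClassifier(n_neighbors=k, metric="euclidean",
                                weights=_squared_inverse_weights)


def make_svm(standardize: bool = True):
    """One-vs-all SVM with a third-degree polynomial kernel, C=1.

    Features are z-scored inside each training fold by default; the
    polynomial kernel is scale-sensitive.
    """
    svm = OneVsRestClassifier(SVC(kernel="poly", degree=SVM_DEGREE, C=SVM_C))
    if standardize:
        return Pipeline([("scale", StandardScaler()), ("svm", svm)])
    return svm


def make_folds(y: np.ndarray, seed: int = 0, n_folds: int = 10) -> list:
    """One stratified partition shared by every outcome of a run."""
    y = np.asarray(y)
    min_class = np.bincount(np.unique(y, return_inverse=True)[1]).min()
    k = min(n_folds, min_class, len(y))
    if k < 2:
        raise ValueError("smallest class too small for cross-validation")
    if k < n_folds:
        logger.warning("fold count lowered from %d to %d (small class)", n_folds, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _cv_outcome(clf, s: np.ndarray, y: np.ndarray, folds, source) -> Outcome:
    pred = cross_val_predict(clf, np.asarray(s, dtype=np.float64), y, cv=folds)
    acc = 100.0 * float(np.mean(pred == y))
    return Outcome(predictions=pred, accuracy=acc, source=source, kind="classifier")


def knn_outcome(s: np.ndarray, y: np.ndarray, folds=None, seed: int = 0,
                source: tuple = ("?", "knn")) -> Outcome:
    """Pooled out-of-fold kNN predictions over stratified 10-fold CV."""
    y = np.asarray(y)
    if folds is None:
        folds = make_folds(y, seed)
    min_train = min(len(tr) for tr, _ in folds)
    return _cv_outcome(make_knn(max_train_size=min_train), s, y, folds, source)


def svm_outcome(s: np.ndarray, y: np.ndarray, folds=None, seed: int = 0,
                standardize: bool = True, source: tuple = ("?", "svm")) -> Outcome:
    """Pooled out-of-fold SVM predictions over stratified 10-fold CV."""
    y = np.asarray(y)
    if folds is None:
        folds = make_folds(y, seed)
    return _cv_outcome(make_svm(standardize=standardize), s, y, folds, source)


def _mode_lowest(values: np.ndarray) -> int:
    """Mode of non-negative integers; ties go to the smallest label."""
    counts = np.bincount(values)
    return int(np.argmax(counts))  # argmax returns the first (lowest) maximum


def imv(c_list: list[Outcome], y: np.ndarray, i_range: tuple[int, int] = IMV_RANGE
        ) -> list[Outcome]:
    """Iterative majority voting over accuracy-sorted classifier outcomes.

    Outcomes are sorted by descending accuracy (stable, preserving input
    order on ties); for each i in ``i_range`` the per-sample mode of the
    top-i outcomes' predictions forms one voted outcome.  Mode ties go to
    the smallest class label.  With the default range 3..8 over 8
    outcomes this yields 6 voted outcomes.
    """
    y = np.asarray(y)
    if len(c_list) < 3:
        raise ValueError("iterative majority voting needs at least 3 outcomes")
    lo, hi = i_range
    if hi > len(c_list):
        logger.warning("IMV range clipped to available outcome count %d", len(c_list))
        hi = len(c_list)
    if lo > hi:
        raise ValueError("empty IMV range after clipping")
    d = len(c_list[0].predictions)
    for c in c_list:
        if len(c.predictions) != d:
            raise ValueError("all outcomes must have equal length")
    order = np.lexsort((np.arange(len(c_list)),
                        -np.array([c.accuracy for c in c_list])))
    preds = np.stack([c_list[t].predictions for t in order])  # sorted, best first
    voted = []
    for i in range(lo, hi + 1):
        v = np.array([_mode_lowest(preds[:i, j]) for j in range(d)])
        voted.append(
            Outcome(
                predictions=v,
                accuracy=100.0 * float(np.mean(v == y)),
                source=("imv", i),
                kind="voted",
            )
        )
    return voted


def compute_metrics(predictions: np.ndarray, y: np.ndarray,
                    n_classes: int | None = None) -> MetricsReport:
    """Accuracy, macro F1, geometric mean of per-class recalls, confusion.

    The geometric mean is the K-th root of the product of the recalls of
    the K classes present in ``y``; a class absent from ``y`` has no
    recall and is excluded with a warning.
    """
    predictions = np.asarray(predictions)
    y = np.asarray(y)
    if n_classes is None:
        n_classes = int(max(predictions.max(), y.max())) + 1
    if predictions.min() < 0 or predictions.max() >= n_classes or y.max() >= n_classes:
        raise ValueError("labels out of range")
    labels = np.arange(n_classes)
    confusion = _confusion_matrix(y, predictions, labels=labels)
    accuracy = 100.0 * float(np.trace(confusion)) / len(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # absent classes handled explicitly below
        f1 = 100.0 * float(_f1_score(y, predictions, labels=labels, average="macro",
                                     zero_division=0))
    support = confusion.sum(axis=1)
    present = support > 0
    if not present.all():
        logger.warning("classes %s absent from y; excluded from geometric mean",
                       labels[~present].tolist())
    recalls = np.diag(confusion)[present] / support[present]
    gm = 100.0 * float(np.prod(recalls) ** (1.0 / present.sum()))
    return MetricsReport(accuracy=accuracy, f1=f1, geometric_mean=gm,
                         confusion=confusion)


def greedy_final(outcomes: list[Outcome], y: np.ndarray,
                 n_classes: int | None = None) -> FusionResult:
    """Select the outcome with maximal accuracy (first on ties).

    The canonical bank holds 14 outcomes (8 classifier-based — the four
    kNN outcomes then the four SVM outcomes — then 6 voted); ties keep
    that order.  Metrics are computed on the winner.
    """
    if not outcomes:
        raise ValueError("no outcomes to fuse")
    y = np.asarray(y)
    accs = np.array([o.accuracy for o in outcomes])
    sorted_order = np.lexsort((np.arange(len(outcomes)), -accs))
    winner_index = int(sorted_order[0])
    winner = outcomes[winner_index]
    metrics = compute_metrics(winner.predictions, y, n_classes=n_classes)
    return FusionResult(
        outcomes=list(outcomes),
        sorted_order=sorted_order,
        winner_index=winner_index,
        final_predictions=winner.predictions.copy(),
        metrics=metrics,
    )
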