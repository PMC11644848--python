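"""Iterative feature selection over four rankers (NCA, Chi2, mRMR, ReliefF).

Each ranker produces a full best-first ordering of the columns of an
n x p feature matrix.  The iterative wrapper then evaluates every prefix
length L in [sv, fv] of that ordering with a 10-fold cross-validated kNN
loss (1 - accuracy) and keeps the prefix achieving the minimal loss,
taking the smallest L on ties.  The defaults sv=100, fv=768 match the
iteration range used on 2048-dimensional deep features; tests and small
fixtures override them.

Rankers
-------
nca      diagonal neighborhood-component-analysis feature weights,
         learned by gradient ascent on the smooth leave-one-out accuracy
         with an L2 penalty on the weights.
chi2     chi-squared statistic of each column (min-shifted, discretized
         into 10 equal-width bins) against the labels.
mrmr     minimum-redundancy-maximum-relevance, mutual-information
         difference variant on 10-bin discretized columns.
relieff  multi-class ReliefF with 10 neighbors, all samples as anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .fuse import make_knn

logger = logging.getLogger(__name__)

__all__ = [
    "RANKERS",
    "RankedIndices",
    "SelectionResult",
    "rank_features",
    "cv_loss",
    "iterative_select",
    "save_selection",
]

RANKERS = ("nca", "chi2", "mrmr", "relieff")
N_BINS = 10  # discretization for chi2 and mutual information
RELIEFF_NEIGHBORS = 10


@dataclass
class RankedIndices:
    """A best-first permutation of column indices with per-column scores."""

    index: np.ndarray  # permutation of range(p)
    ranker: str
    scores: np.ndarray  # score per original column (higher = better)

    def __post_init__(self):
        p = len(self.index)
        if sorted(self.index.tolist()) != list(range(p)):
            raise ValueError("index must be a permutation of range(p)")


@dataclass
class SelectionResult:
    """Outcome of one iterative selection run."""

    s: np.ndarray  # (n, chosen_length) selected feature matrix
    selected_idx: np.ndarray  # chosen columns in ranked order
    loss_curve: np.ndarray  # loss per candidate length sv..fv
    chosen_length: int
    sv: int
    fv: int
    ranker: str

    def __post_init__(self):
        if not self.sv <= self.chosen_length <= self.fv:
            raise ValueError("chosen_length outside [sv, fv]")
        if len(self.loss_curve) != self.fv - self.sv + 1:
            raise ValueError("loss curve length mismatch")


# ---------------------------------------------------------------------------
# rankers


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains NaN or infinite values")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(X) < len(np.unique(y)):
        raise ValueError("need at least one sample per class")
    return X, y


def _order_desc(scores: np.ndarray) -> np.ndarray:
    """Descending-score order; ties broken by ascending column index."""
    return np.lexsort((np.arange(len(scores)), -scores))


def _discretize(X: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Columnwise equal-width binning into integer codes 0..n_bins-1."""
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    codes = np.floor((X - lo) / span * n_bins).astype(np.int64)
    return np.minimum(codes, n_bins - 1)


def _chi2_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Chi-squared statistic of each binned column against the labels."""
    codes = _discretize(X - X.min(axis=0))  # min-shift, then bin
    classes, y_codes = np.unique(y, return_inverse=True)
    k, n = len(classes), len(y)
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        obs = np.zeros((N_BINS, k))
        np.add.at(obs, (codes[:, j], y_codes), 1.0)
        obs = obs[obs.sum(axis=1) > 0]
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
        with np.errstate(invalid="ignore", divide="ignore"):
            cell = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
        scores[j] = cell.sum()
    return scores


def _entropy_from_counts(counts: np.ndarray, axis=None) -> np.ndarray:
    n = counts.sum(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n
        term = np.where(p > 0, p * np.log(p), 0.0)
    return -term.sum(axis=axis)


def _mi_against_all(codes: np.ndarray, target: np.ndarray, n_target: int) -> np.ndarray:
    """Mutual information (nats) of every column of `codes` with `target`."""
    n, p = codes.shape
    joint = np.zeros((p, N_BINS * n_target))
    flat = codes * n_target + target[:, None]
    np.add.at(joint, (np.broadcast_to(np.arange(p), (n, p)), flat), 1.0)
    joint = joint.reshape(p, N_BINS, n_target)
    h_x = _entropy_from_counts(joint.sum(axis=2), axis=1)
    h_t = _entropy_from_counts(joint.sum(axis=1), axis=1)
    h_xt = _entropy_from_counts(joint.reshape(p, -1), axis=1)
    return np.maximum(h_x + h_t - h_xt, 0.0)


def _mrmr_order(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy mutual-information-difference mRMR over all p columns."""
    codes = _discretize(X)
    _, y_codes = np.unique(y, return_inverse=True)
    p = X.shape[1]
    relevance = _mi_against_all(codes, y_codes, y_codes.max() + 1)
    order = np.empty(p, dtype=np.int64)
    chosen = np.zeros(p, dtype=bool)
    redundancy_sum = np.zeros(p)
    # first pick: maximal relevance (ties -> lowest index via lexsort)
    current = int(_order_desc(relevance)[0])
    order[0] = current
    chosen[current] = True
    for step in range(1, p):
        redundancy_sum += _mi_against_all(codes, codes[:, current], N_BINS)
        crit = relevance - redundancy_sum / step
        crit[chosen] = -np.inf
        current = int(_order_desc(crit)[0])
        order[step] = current
        chosen[current] = True
    scores = np.empty(p)
    scores[order] = np.arange(p, 0, -1)  # rank-based scores, best-first
    return order, scores


def _relieff_scores(X: np.ndarray, y: np.ndarray, k: int = RELIEFF_NEIGHBORS) -> np.ndarray:
    """Multi-class ReliefF weights, every sample used as an anchor."""
    n, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    classes, y_codes = np.unique(y, return_inverse=True)
    priors = np.bincount(y_codes) / n
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros(p)
    for i in range(n):
        ci = y_codes[i]
        hits = np.flatnonzero(y_codes == ci)
        hits = hits[hits != i]
        kh = min(k, len(hits))
        if kh:
            nearest = hits[np.argsort(d2[i, hits], kind="stable")[:kh]]
            w -= (np.abs(X[nearest] - X[i]) / span).mean(axis=0)
        for cm in range(len(classes)):
            if cm == ci:
                continue
            miss = np.flatnonzero(y_codes == cm)
            km = min(k, len(miss))
            if not km:
                continue
            nearest = miss[np.argsort(d2[i, miss], kind="stable")[:km]]
            coef = priors[cm] / (1.0 - priors[ci])
            w += coef * (np.abs(X[nearest] - X[i]) / span).mean(axis=0)
    return w / n


def _nca_scores(X: np.ndarray, y: np.ndarray, reg: float = 1.0, lr: float = 0.1,
                n_iter: int = 60) -> np.ndarray:
    """Diagonal NCA feature weights learned by projected gradient ascent.

    Maximizes the expected leave-one-out accuracy of a stochastic nearest
    neighbor rule under the weighted L1 distance d(i,j) = sum_r w_r^2
    |x_ir - x_jr|, minus reg * sum w_r^2; weights are kept non-negative
    and returned as ranking scores.
    """
    n, p = X.shape
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    absdiff = np.abs(Z[:, None, :] - Z[None, :, :])  # (n, n, p)
    same = (y[:, None] == y[None, :]).astype(np.float64)
    np.fill_diagonal(same, 0.0)
    w = np.ones(p)
    reg_n = reg / n  # penalty scaled per sample, fscnca-style
    for _ in range(n_iter):
        d = absdiff @ (w**2)  # (n, n)
        np.fill_diagonal(d, np.inf)
        logits = -d
        logits -= logits.max(axis=1, keepdims=True)
        pij = np.exp(logits)
        pij /= pij.sum(axis=1, keepdims=True)
        pi = (pij * same).sum(axis=1)  # prob of correct neighbor per anchor
        coef = pi[:, None] * pij - pij * same  # d(objective)/d d_ij * (-1)
        grad = (2.0 * w / n) * np.einsum("ij,ijr->r", coef, absdiff) - 2.0 * reg_n * w
        w = np.maximum(w + lr * grad, 0.0)
    return w


def rank_features(X: np.ndarray, y: np.ndarray, ranker: str) -> RankedIndices:
    """Order all columns best-first under the named ranker.

    Ties are broken by ascending column index; a constant matrix yields
    an all-tied ranking in index order.
    """
    X, y = _check_xy(X, y)
    if ranker == "chi2":
        scores = _chi2_scores(X, y)
        order = _order_desc(scores)
    elif ranker == "relieff":
        scores = _relieff_scores(X, y)
        order = _order_desc(scores)
    elif ranker == "nca":
        scores = _nca_scores(X, y)
        order = _order_desc(scores)
    elif ranker == "mrmr":
        order, scores = _mrmr_order(X, y)
    else:
        raise ValueError(f"unknown ranker {ranker!r}; choose from {RANKERS}")
    return RankedIndices(index=order, ranker=ranker, scores=scores)


# ---------------------------------------------------------------------------
# iterative wrapper


def _make_folds(y: np.ndarray, seed: int, n_folds: int = 10) -> list:
    """Stratified folds, lowering the fold count for small classes."""
    min_class = np.bincount(np.unique(y, return_inverse=True)[1]).min()
    k = min(n_folds, min_class, len(y))
    if k < 2:
        raise ValueError("smallest class too small for cross-validation")
    if k < n_folds:
        logger.warning("fold count lowered from %d to %d (small class)", n_folds, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cv_loss(sf: np.ndarray, y: np.ndarray, folds=None, seed: int = 0) -> float:
    """1 - stratified 10-fold CV accuracy of the pipeline's kNN classifier.

    ``folds`` may carry a precomputed fold list so that every candidate
    feature length within one selection run is judged on identical folds.
    """
    sf = np.asarray(sf, dtype=np.float64)
    if sf.ndim == 1:
        sf = sf[:, None]
    y = np.asarray(y)
    if folds is None:
        folds = _make_folds(y, seed)
    min_train = min(len(tr) for tr, _ in folds)
    pred = cross_val_predict(make_knn(max_train_size=min_train), sf, y, cv=folds)
    return float(1.0 - np.mean(pred == y))


def iterative_select(X: np.ndarray, y: np.ndarray, ranker: str, sv: int = 100,
                     fv: int = 768, seed: int = 0) -> SelectionResult:
    """Choose the best prefix length of a ranked column ordering.

    Candidate lengths run sv..fv inclusive; each prefix of the ranking is
    scored with ``cv_loss`` on one shared fold partition, and the length
    with minimal loss wins (smallest length on ties — smaller feature
    sets are preferable).  ``fv`` is lowered to p when the matrix is
    narrower than requested.
    """
    X, y = _check_xy(X, y)
    p = X.shape[1]
    if sv > fv:
        raise ValueError("sv must not exceed fv")
    if sv < 1:
        raise ValueError("sv must be >= 1")
    if fv > p:
        logger.warning("fv lowered from %d to %d (matrix has %d columns)", fv, p, p)
        fv = p
        if sv > fv:
            raise ValueError("sv exceeds the number of available columns")
    ranked = rank_features(X, y, ranker)
    folds = _make_folds(y, seed)
    lengths = np.arange(sv, fv + 1)
    losses = np.empty(len(lengths))
    for i, length in enumerate(lengths):
        losses[i] = cv_loss(X[:, ranked.index[:length]], y, folds=folds)
    best = int(np.argmin(losses))  # np.argmin returns the first minimum
    chosen = int(lengths[best])
    idx = ranked.index[:chosen].copy()
    return SelectionResult(
        s=X[:, idx],
        selected_idx=idx,
        loss_curve=losses,
        chosen_length=chosen,
        sv=sv,
        fv=fv,
        ranker=ranker,
    )


def save_selection(result: SelectionResult, path) -> None:
    np.savez(
        path,
        s=result.s,
        selected_idx=result.selected_idx,
        loss_curve=result.loss_curve,
        chosen_length=result.chosen_length,
        sv=result.sv,
        fv=result.fv,
        ranker=result.ranker,
    )
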