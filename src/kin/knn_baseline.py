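"""Plain k-nearest-neighbor baseline.

Unweighted Minkowski-distance KNN with the neighbor count restricted to odd
values up to floor(sqrt(n_train)) — the odd-k convention removes voting
ties in binary classification.  Standardization, fold construction and the
cross-validation loss are deliberately identical to the KIN classifier so
that a KIN-vs-KNN comparison isolates the effect of the contribution-
weighted dissimilarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .kin_core import _cv_splits, _standardizer
from .metrics import misclassification_rate

__all__ = ["KnnModel", "minkowski_distance", "fit_knn", "predict_knn"]


def minkowski_distance(xa, xb, q: float = 2.0) -> float:
    """(sum_j |xa_j - xb_j|^q)^(1/q); q=2 Euclidean, q=1 Manhattan."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    if xa.shape != xb.shape:
        raise ValueError("xa and xb must have equal length")
    if q <= 0:
        raise ValueError("q must be positive")
    return float(np.sum(np.abs(xa - xb) ** q) ** (1.0 / q))


@dataclass
class KnnModel:
    train_X: np.ndarray  # standardized
    train_y: np.ndarray
    k_selected: int
    q_order: float
    mean_: np.ndarray
    scale_: np.ndarray
    seed: int = 0


def _vote(order_row, dists_row, train_y, k):
    idx = order_row[:k]
    labels = train_y[idx]
    k1 = int(np.sum(labels == 0))
    k2 = k - k1
    if k1 != k2:
        return 0 if k1 > k2 else 1
    # unreachable for odd k; kept for even-k use of the helper
    s0 = dists_row[idx][labels == 0].sum()
    s1 = dists_row[idx][labels == 1].sum()
    return 0 if s0 <= s1 else 1


def fit_knn(train_X, train_y, seed: int = 0, q: float = 2.0, n_folds: int = 5) -> KnnModel:
    """Select the odd neighbor count by stratified 5-fold CV on weighted MC."""
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y).astype(int)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("train_X must be 2-d with one label per row")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training data")
    mean, scale = _standardizer(X)
    Xs = (X - mean) / scale
    n = len(y)
    kmax = max(1, math.isqrt(n))
    k_grid = list(range(1, kmax + 1, 2))
    if len(y) < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} training rows for {n_folds}-fold CV")
    errs = np.zeros(len(k_grid))
    n_used = 0
    for tr, va in _cv_splits(Xs, y, n_folds, seed):
        if len(np.unique(y[tr])) < 2:
            continue
        D = cdist(Xs[va], Xs[tr], metric="minkowski", p=q)
        order = np.argsort(D, axis=1, kind="stable")
        for ki, k in enumerate(k_grid):
            kk = min(k, len(tr))
            preds = np.array([_vote(order[i], D[i], y[tr], kk) for i in range(len(va))])
            errs[ki] += misclassification_rate(y[va], preds)
        n_used += 1
    if n_used == 0:
        raise ValueError("every CV fold had a single-class training part")
    errs /= n_used
    k_sel = k_grid[int(np.argmin(errs))]
    return KnnModel(train_X=Xs, train_y=y, k_selected=k_sel, q_order=q,
                    mean_=mean, scale_=scale, seed=seed)


def predict_knn(model: KnnModel, test_X) -> np.ndarray:
    X = np.asarray(test_X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.train_X.shape[1]:
        raise ValueError(f"expected {model.train_X.shape[1]} features")
    Xs = (X - model.mean_) / model.scale_
    D = cdist(Xs, model.train_X, metric="minkowski", p=model.q_order)
    order = np.argsort(D, axis=1, kind="stable")
    k = model.k_selected
    return np.array([_vote(order[i], D[i], model.train_y, k) for i in range(len(Xs))])
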