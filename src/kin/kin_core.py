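"""The K important neighbors (KIN) classifier.

KIN is a hybrid of penalized logistic regression and nearest-neighbor
voting.  A SCAD-penalized logistic fit on the training data yields a sparse
coefficient vector; each feature's contribution weight is

    w_j = |beta_j| / sum_j |beta_j|,

so noise features (exact-zero coefficients) receive weight zero and drop
out of the dissimilarity

    d(x_a, x_b) = sqrt( sum_j w_j (x_aj - x_bj)^2 ).

A query is assigned the majority label among its k smallest-dissimilarity
training points; on an even-k split vote, the class whose tied neighbors
have the smaller summed dissimilarity wins (equal sums resolve to class 0).
The neighbor count k is chosen by stratified 5-fold cross-validation over
both even and odd values up to floor(sqrt(n_train)).

Because the weights annihilate zero-coefficient features, KIN performs
dimension reduction and classification in one step: only the features the
penalized fit kept can influence any prediction.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold, StratifiedKFold

from .metrics import misclassification_rate
from .scad_logistic import FittedScad, PenaltyConfig, cv_select_lambda

__all__ = [
    "NullModelError",
    "WeightVector",
    "KinModel",
    "feature_weights",
    "weighted_distance",
    "vote_and_break_ties",
    "select_k",
    "fit_kin",
    "predict_kin",
    "model_to_json",
    "model_from_json",
]


class NullModelError(ValueError):
    """Raised when every penalized coefficient is zero, so no contribution
    weights exist.  Callers should fall back to a majority-class predictor."""


@dataclass
class WeightVector:
    """Normalized, nonnegative feature-contribution weights."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.w)


def feature_weights(coefs) -> WeightVector:
    """Contribution weights from penalized coefficients: |b_j| / sum|b_j|."""
    coefs = np.asarray(getattr(coefs, "coefs", coefs), dtype=float)
    total = np.abs(coefs).sum()
    if total == 0:
        raise NullModelError(
            "all penalized coefficients are zero (null model); "
            "fall back to the training majority class"
        )
    return WeightVector(np.abs(coefs) / total)


def weighted_distance(xa, xb, w) -> float:
    """Contribution-weighted Euclidean dissimilarity between two points."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    wv = np.asarray(getattr(w, "w", w), dtype=float)
    if not (xa.shape == xb.shape == wv.shape):
        raise ValueError("xa, xb and w must have equal length")
    return float(np.sqrt(np.sum(wv * (xa - xb) ** 2)))


def vote_and_break_ties(neighbor_labels, neighbor_dists) -> int:
    """Majority vote over the k neighbors; an even split is resolved in
    favour of the class with the smaller summed dissimilarity, and an exact
    sum tie resolves to class 0."""
    labels = np.asarray(neighbor_labels).astype(int)
    dists = np.asarray(neighbor_dists, dtype=float)
    if labels.size == 0 or labels.shape != dists.shape:
        raise ValueError("labels and dists must be nonempty and equal-length")
    k1 = int(np.sum(labels == 0))
    k2 = labels.size - k1
    if k1 > k2:
        return 0
    if k2 > k1:
        return 1
    sum0 = float(dists[labels == 0].sum())
    sum1 = float(dists[labels == 1].sum())
    return 0 if sum0 <= sum1 else 1


def _pairwise_weighted(A, B, w) -> np.ndarray:
    """All-pairs weighted Euclidean distances (rows of A vs rows of B)."""
    sw = np.sqrt(np.asarray(getattr(w, "w", w), dtype=float))
    return cdist(A * sw, B * sw, metric="euclidean")


def _predict_from_distances(D, train_y, k) -> np.ndarray:
    # stable sort: exact distance ties resolve by training-row index
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    preds = np.empty(D.shape[0], dtype=int)
    for i in range(D.shape[0]):
        idx = order[i]
        preds[i] = vote_and_break_ties(train_y[idx], D[i, idx])
    return preds


def _cv_splits(X, y, n_folds, seed, stratified=False):
    """Random K-fold assignment; plain random division by default, mirroring
    the method's description of cross-validation.  Stratified folds are
    available for callers that need guaranteed class balance."""
    if stratified:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return list(skf.split(X, y))
    return list(KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(X))


def select_k(
    train_X, train_y, w, k_grid, n_folds: int = 5, seed: int = 0,
    stratified: bool = False,
) -> int:
    """Neighbor count minimizing mean cross-validated weighted MC.

    Ties between k values resolve toward the smallest k (parsimony).
    Folds are a plain random division by default; a fold whose training
    part contains a single class is skipped.
    """
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y).astype(int)
    k_grid = sorted(int(k) for k in k_grid)
    if len(k_grid) == 0 or k_grid[0] < 1:
        raise ValueError("k_grid must contain positive integers")
    if len(y) < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} training rows for {n_folds}-fold CV")
    errs = np.zeros(len(k_grid))
    n_used = 0
    for tr, va in _cv_splits(X, y, n_folds, seed, stratified):
        if len(np.unique(y[tr])) < 2:
            continue
        D = _pairwise_weighted(X[va], X[tr], w)
        order = np.argsort(D, axis=1, kind="stable")
        for ki, k in enumerate(k_grid):
            kk = min(k, len(tr))
            preds = np.empty(len(va), dtype=int)
            for i in range(len(va)):
                idx = order[i, :kk]
                preds[i] = vote_and_break_ties(y[tr][idx], D[i, idx])
            errs[ki] += misclassification_rate(y[va], preds)
        n_used += 1
    if n_used == 0:
        raise ValueError("every CV fold had a single-class training part")
    errs /= n_used
    return k_grid[int(np.argmin(errs))]


@dataclass
class KinModel:
    """A fitted KIN classifier.

    Stores the standardized training data, the contribution weights, the
    selected neighbor count, the standardization statistics needed to map
    new data onto the training scale and the underlying penalized fit.
    ``fallback_label`` is set when the penalized fit selected no features,
    in which case the model predicts that (majority) class everywhere.
    """

    train_X: np.ndarray
    train_y: np.ndarray
    weights: WeightVector | None
    k_selected: int
    k_grid: list[int]
    mean_: np.ndarray
    scale_: np.ndarray
    scad: FittedScad | None = None
    seed: int = 0
    fallback_label: int | None = None
    feature_names: list[str] | None = field(default=None, repr=False)

    @property
    def is_null(self) -> bool:
        return self.fallback_label is not None


def _standardizer(X):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns carry no information
    return mean, scale


def fit_kin(
    train_X,
    train_y,
    cfg: PenaltyConfig | None = None,
    seed: int = 0,
    k_grid=None,
) -> KinModel:
    """Fit the full KIN pipeline.

    Standardize features -> cross-validated SCAD logistic fit ->
    contribution weights -> cross-validated neighbor count.  If the
    penalized fit keeps no feature, the model degrades to a majority-class
    predictor with a warning.
    """
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y).astype(int)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("train_X must be 2-d with one label per row")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training data")
    cfg = cfg or PenaltyConfig(seed=seed)
    mean, scale = _standardizer(X)
    Xs = (X - mean) / scale
    fit = cv_select_lambda(Xs, y, cfg)
    n = len(y)
    kmax = max(1, math.isqrt(n))
    k_grid = sorted(k_grid) if k_grid is not None else list(range(1, kmax + 1))
    try:
        w = feature_weights(fit.coefs)
    except NullModelError:
        counts = np.bincount(y, minlength=2)
        majority = 0 if counts[0] >= counts[1] else 1
        warnings.warn(
            "SCAD selected no features; KIN falls back to predicting the "
            f"training majority class ({majority})",
            RuntimeWarning,
            stacklevel=2,
        )
        return KinModel(
            train_X=Xs, train_y=y, weights=None, k_selected=k_grid[0],
            k_grid=k_grid, mean_=mean, scale_=scale, scad=fit, seed=seed,
            fallback_label=majority,
        )
    k = select_k(Xs, y, w, k_grid, n_folds=cfg.n_folds, seed=seed)
    return KinModel(
        train_X=Xs, train_y=y, weights=w, k_selected=k, k_grid=k_grid,
        mean_=mean, scale_=scale, scad=fit, seed=seed,
    )


def predict_kin(model: KinModel, test_X) -> np.ndarray:
    """Predict labels for the rows of ``test_X``.

    Test features are standardized with the training statistics stored on
    the model; each row is classified independently.
    """
    X = np.asarray(test_X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.train_X.shape[1]:
        raise ValueError(
            f"expected {model.train_X.shape[1]} features, got {X.shape[1] if X.ndim == 2 else 'non-matrix'}"
        )
    if model.is_null:
        return np.full(X.shape[0], model.fallback_label, dtype=int)
    Xs = (X - model.mean_) / model.scale_
    D = _pairwise_weighted(Xs, model.train_X, model.weights)
    return _predict_from_distances(D, model.train_y, model.k_selected)


# ---------------------------------------------------------------------------
# JSON persistence
# ---------------------------------------------------------------------------


def model_to_json(model: KinModel) -> str:
    """Serialize a fitted model (training data included) to a JSON string."""
    doc = {
        "model_type": "kin",
        "train_X": model.train_X.tolist(),
        "train_y": model.train_y.tolist(),
        "weights": None if model.weights is None else model.weights.w.tolist(),
        "support": None if model.weights is None else model.weights.support.tolist(),
        "k_selected": model.k_selected,
        "k_grid": list(model.k_grid),
        "mean": model.mean_.tolist(),
        "scale": model.scale_.tolist(),
        "seed": model.seed,
        "fallback_label": model.fallback_label,
        "lam_selected": None if model.scad is None else model.scad.lam_selected,
        "intercept": None if model.scad is None else model.scad.intercept,
        "coefs": None if model.scad is None else model.scad.coefs.tolist(),
        "feature_names": model.feature_names,
    }
    return json.dumps(doc, sort_keys=True)


def model_from_json(text: str) -> KinModel:
    doc = json.loads(text)
    if doc.get("model_type") != "kin":
        raise ValueError("not a KIN model document")
    scad = None
    if doc["coefs"] is not None:
        scad = FittedScad(
            intercept=doc["intercept"],
            coefs=np.asarray(doc["coefs"], dtype=float),
            lam_selected=doc["lam_selected"],
        )
    return KinModel(
        train_X=np.asarray(doc["train_X"], dtype=float),
        train_y=np.asarray(doc["train_y"], dtype=int),
        weights=None if doc["weights"] is None else WeightVector(np.asarray(doc["weights"])),
        k_selected=int(doc["k_selected"]),
        k_grid=[int(k) for k in doc["k_grid"]],
        mean_=np.asarray(doc["mean"], dtype=float),
        scale_=np.asarray(doc["scale"], dtype=float),
        scad=scad,
        seed=int(doc["seed"]),
        fallback_label=doc["fallback_label"],
        feature_names=doc.get("feature_names"),
    )
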