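"""Cross-validated ROC/AUC evaluation of tumor/normal classification.

The harness (stratified folds, rank-based AUC, CV loop) is the computation
of record; classifiers plug in through a minimal fit/score contract.  Two
reference classifiers are provided: nearest-centroid and k-nearest-neighbor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


def stratified_kfold(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per sample).

    Within each class, samples are shuffled and dealt round-robin, so class
    balance per fold is within +/-1.
    """
    labels = np.asarray(labels)
    n = labels.size
    if k > n:
        raise ValueError("k exceeds number of samples")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    offset = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        folds[idx] = (np.arange(idx.size) + offset) % k
        offset += idx.size  # stagger classes so small folds stay balanced
    return folds


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) formulation; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) coordinates at every distinct threshold, descending."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order])
    fps = np.cumsum(~labels[order])
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / max(labels.sum(), 1)]
    fpr = np.r_[0.0, fps[distinct] / max((~labels).sum(), 1)]
    return np.column_stack([fpr, tpr])


class NearestCentroidClassifier:
    """Scores by (distance to negative centroid) - (distance to positive)."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NearestCentroidClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(bool)
        self.pos_ = X[y].mean(axis=0)
        self.neg_ = X[~y].mean(axis=0)
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d_pos = np.linalg.norm(X - self.pos_, axis=1)
        d_neg = np.linalg.norm(X - self.neg_, axis=1)
        return d_neg - d_pos


class KNNClassifier:
    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNClassifier":
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y).astype(float)
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d = np.linalg.norm(X[:, None, :] - self.X_[None, :, :], axis=2)
        k = min(self.k, self.X_.shape[0])
        nearest = np.argsort(d, axis=1)[:, :k]
        return self.y_[nearest].mean(axis=1)


@dataclass
class CVResult:
    classifier: str
    fold_auc: list[float]
    mean_auc: float
    folds: np.ndarray


def cv_auc(
    X: np.ndarray,
    labels: np.ndarray,
    classifier,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """k-fold cross-validated AUC: train on k-1 folds, score the held-out
    fold, AUC per fold and their mean.  Folds lacking a class are skipped
    with a warning."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(bool)
    folds = stratified_kfold(labels, k, seed)
    aucs: list[float] = []
    for f in range(k):
        test = folds == f
        if labels[test].all() or not labels[test].any():
            warnings.warn(f"fold {f}: single-class test set skipped")
            continue
        clf = classifier.fit(X[~test], labels[~test])
        scores = clf.score_samples(X[test])
        aucs.append(roc_auc(scores, labels[test]))
    name = type(classifier).__name__
    return CVResult(name, aucs, float(np.mean(aucs)) if aucs else float("nan"), folds)
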