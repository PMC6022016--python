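"""Confusion-matrix metrics, stratified k-fold cross-validation and ROC.

Fall detection treats ``fall`` as the positive class: sensitivity
TP/(TP+FN) is the fraction of fall frames caught, specificity TN/(TN+FP)
the fraction of no-fall frames correctly rejected.  Cross-validation is
stratified per class with deterministic seeded fold assignment, and the ROC
curve is a standard threshold sweep over the ensemble's signed vote margins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import BoostedEnsemble, predict, train_boosted

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "stratified_folds",
    "kfold_cv",
    "roc_points",
    "roc_auc",
]


@dataclass
class ConfusionCounts:
    """Binary counts w.r.t. a positive class, plus the full per-class matrix."""

    TP: int
    FN: int
    TN: int
    FP: int
    positive: object
    classes: list
    matrix: np.ndarray  # (C, C), rows = true class, cols = predicted

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP

    def matrix_dict(self) -> dict:
        return {
            str(t): {str(p): int(self.matrix[i, j]) for j, p in enumerate(self.classes)}
            for i, t in enumerate(self.classes)
        }


def confusion(y_true, y_pred, positive="fall", classes=None) -> ConfusionCounts:
    """Counts per the fall-detection reading: TP = falls caught, FN = falls
    missed, TN = no-falls correctly identified, FP = no-falls missed."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()), key=str)
    else:
        classes = list(classes)
        unknown = (set(y_true.tolist()) | set(y_pred.tolist())) - set(classes)
        if unknown:
            raise ValueError(f"labels {unknown} not in class list {classes}")
    idx = {c: i for i, c in enumerate(classes)}
    C = len(classes)
    mat = np.zeros((C, C), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[idx[t], idx[p]] += 1
    pos_true = y_true == positive
    pos_pred = y_pred == positive
    return ConfusionCounts(
        TP=int(np.sum(pos_true & pos_pred)),
        FN=int(np.sum(pos_true & ~pos_pred)),
        TN=int(np.sum(~pos_true & ~pos_pred)),
        FP=int(np.sum(~pos_true & pos_pred)),
        positive=positive,
        classes=classes,
        matrix=mat,
    )


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of correctly labelled samples (multi-class: matrix trace)."""
    return float(np.trace(c.matrix) / c.matrix.sum())


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN with a warning when there are no positives."""
    if c.TP + c.FN == 0:
        warnings.warn("sensitivity undefined: no positive samples", stacklevel=2)
        return float("nan")
    return c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN with a warning when there are no negatives."""
    if c.TN + c.FP == 0:
        warnings.warn("specificity undefined: no negative samples", stacklevel=2)
        return float("nan")
    return c.TN / (c.TN + c.FP)


@dataclass
class MetricsReport:
    """Pooled cross-validation metrics plus per-fold breakdown."""

    accuracy: float
    sensitivity: float
    specificity: float
    confusion: ConfusionCounts
    fold_accuracies: list[float] = field(default_factory=list)
    roc: list[tuple[float, float]] | None = None
    auc: float | None = None
    n_samples: int = 0
    classes: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion_matrix": self.confusion.matrix_dict(),
            "fold_accuracies": self.fold_accuracies,
            "auc": self.auc,
            "roc": self.roc,
            "n_samples": self.n_samples,
            "classes": [str(c) for c in self.classes],
            "metadata": self.metadata,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def stratified_folds(y, folds: int, seed: int = 0) -> np.ndarray:
    """Deterministic per-class round-robin fold assignment."""
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    assign = np.empty(len(y), dtype=int)
    for c in sorted(set(y.tolist()), key=str):
        idx = np.nonzero(y == c)[0]
        if idx.size < folds:
            raise ValueError(
                f"class {c!r} has {idx.size} samples, fewer than {folds} folds"
            )
        perm = rng.permutation(idx)
        assign[perm] = np.arange(perm.size) % folds
    return assign


def kfold_cv(
    X,
    y,
    folds: int = 10,
    seed: int = 0,
    base: str = "full_tree",
    rounds: int = 10,
    max_depth: int | None = None,
    min_leaf: int = 1,
    positive="fall",
) -> MetricsReport:
    """Stratified k-fold cross-validation of a boosted ensemble.

    Predictions from all test folds are pooled into one confusion matrix;
    two-class runs also pool the signed margins into a ROC curve.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    assign = stratified_folds(y, folds, seed)
    pred = np.empty(len(y), dtype=y.dtype)
    margins = np.empty(len(y))
    fold_acc: list[float] = []
    for f in range(folds):
        test = assign == f
        ens = train_boosted(
            X[~test], y[~test], K=rounds, base=base,
            max_depth=max_depth, min_leaf=min_leaf, seed=seed,
        )
        labels, m = predict(ens, X[test])
        pred[test] = labels
        margins[test] = m
        fold_acc.append(float(np.mean(labels == y[test])))
    conf = confusion(y, pred, positive=positive)
    two_class = len(set(y.tolist())) == 2
    roc = auc_val = None
    if two_class:
        roc = roc_points(margins, y, positive=positive)
        auc_val = roc_auc(roc)
    return MetricsReport(
        accuracy=accuracy(conf),
        sensitivity=sensitivity(conf),
        specificity=specificity(conf),
        confusion=conf,
        fold_accuracies=fold_acc,
        roc=roc,
        auc=auc_val,
        n_samples=len(y),
        classes=conf.classes,
        metadata={"folds": folds, "seed": seed, "base": base, "rounds": rounds},
    )


def roc_points(margins, y_true, positive="fall") -> list[tuple[float, float]]:
    """(FPR, TPR) pairs from a threshold sweep over the margin scores.

    Monotone from (0, 0) to (1, 1); tied scores move diagonally in one step.
    """
    margins = np.asarray(margins, dtype=np.float64)
    y_true = np.asarray(y_true)
    pos = y_true == positive
    P = int(pos.sum())
    N = int((~pos).sum())
    if P == 0 or N == 0:
        raise ValueError("ROC needs at least one positive and one negative sample")
    order = np.argsort(-margins, kind="stable")
    sorted_pos = pos[order]
    sorted_m = margins[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    last = np.r_[sorted_m[1:] != sorted_m[:-1], True]  # end of each tie group
    pts = [(0.0, 0.0)]
    for i in np.nonzero(last)[0]:
        pts.append((fps[i] / N, tps[i] / P))
    return pts


def roc_auc(points: list[tuple[float, float]]) -> float:
    """Trapezoidal area under a ROC point list."""
    pts = np.asarray(points, dtype=np.float64)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))
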