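"""Gain-ratio decision trees and boosted ensembles, from scratch.

The base learner is a C4.5-style binary tree over continuous attributes:
at each node every midpoint between consecutive distinct sorted attribute
values is a candidate threshold, scored by the gain ratio

    GainRatio(X, T) = Gain(X, T) / SplitInfo(X, T),

where Gain is the weighted information gain in bits and SplitInfo is the
entropy of the split proportions.  Candidates need strictly positive gain
and split info; ties break to the lowest attribute index, then the lowest
threshold, so training is deterministic.

Two boosted configurations are exposed: boosted full trees (unlimited-depth
gain-ratio trees, the stronger frame classifier) and classic AdaBoost over
depth-1 stumps.  Boosting is discrete AdaBoost for two classes and SAMME for
three, with the final decision the sign (or argmax) of the alpha-weighted
vote F(x) = sum_k alpha_k phi_k(x).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SplitCandidate",
    "DecisionTree",
    "BoostedEnsemble",
    "entropy",
    "split_info",
    "best_split",
    "grow_tree",
    "train_boosted",
    "predict",
]

_EPS = 1e-12


def entropy(counts) -> float:
    """Shannon entropy, in bits, of class counts or weights."""
    c = np.asarray(counts, dtype=np.float64)
    total = c.sum()
    if total <= 0:
        raise ValueError("entropy of an empty set is undefined")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def split_info(sizes) -> float:
    """Entropy of partition proportions |Ti|/|T|, in bits."""
    s = np.asarray(sizes, dtype=np.float64)
    if (s <= 0).any():
        raise ValueError("all partition sizes must be positive")
    return entropy(s)


@dataclass(frozen=True)
class SplitCandidate:
    attribute: int
    threshold: float
    gain: float
    split_info: float
    gain_ratio: float


def best_split(
    X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> SplitCandidate | None:
    """Highest-gain-ratio (attribute, threshold) over all midpoint candidates.

    Thresholds are midpoints between consecutive distinct sorted values of
    each attribute; a candidate must have Gain > 0 and SplitInfo > 0.
    Returns ``None`` when no admissible candidate exists (e.g. a pure node or
    all-constant attributes).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n, d = X.shape
    if n < 2:
        return None
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        return None
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    total_w = w.sum()
    onehot = np.zeros((n, classes.size))
    onehot[np.arange(n), y_idx] = w
    parent_h = entropy(onehot.sum(axis=0))

    best: SplitCandidate | None = None
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        v = X[order, j]
        cw = np.cumsum(onehot[order], axis=0)  # class weights left of each cut
        cut = np.nonzero(v[1:] > v[:-1])[0]  # split after position i
        if cut.size == 0:
            continue
        class_tot = cw[-1]
        wl = cw[cut].sum(axis=1)
        wr = total_w - wl
        hl = _entropy_rows(cw[cut])
        hr = _entropy_rows(class_tot - cw[cut])
        gain = parent_h - (wl * hl + wr * hr) / total_w
        pl = wl / total_w
        pr = wr / total_w
        si = -(_xlog2(pl) + _xlog2(pr))
        ok = (gain > _EPS) & (si > _EPS)
        if not ok.any():
            continue
        gr = np.where(ok, gain / np.where(si > 0, si, 1.0), -np.inf)
        # ties (equal gain ratio up to rounding) break to the lowest
        # threshold within an attribute, then the lowest attribute index
        top = gr.max()
        tol = 1e-12 * max(1.0, abs(top))
        i = int(np.argmax(gr >= top - tol))
        if best is None or gr[i] > best.gain_ratio + tol:
            thr = 0.5 * (v[cut[i]] + v[cut[i] + 1])
            best = SplitCandidate(
                attribute=j,
                threshold=float(thr),
                gain=float(gain[i]),
                split_info=float(si[i]),
                gain_ratio=float(gr[i]),
            )
    return best


def _xlog2(p: np.ndarray) -> np.ndarray:
    return np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)


def _entropy_rows(cw: np.ndarray) -> np.ndarray:
    tot = cw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, cw / np.where(tot > 0, tot, 1.0), 0.0)
    return -_xlog2(p).sum(axis=1)


@dataclass
class _Node:
    # leaf when attribute is None
    attribute: int | None = None
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    label: object = None
    probs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        if self.attribute is None:
            return {"leaf": True, "label": self.label, "probs": self.probs}
        return {
            "leaf": False,
            "attribute": int(self.attribute),
            "threshold": float(self.threshold),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        if d["leaf"]:
            return cls(label=d["label"], probs=dict(d["probs"]))
        return cls(
            attribute=d["attribute"],
            threshold=d["threshold"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


class DecisionTree:
    """Binary gain-ratio tree; internal nodes route ``x[attr] <= thr`` left."""

    def __init__(self, root: _Node, classes: list):
        self.root = root
        self.classes = list(classes)

    def predict_one(self, x: np.ndarray):
        node = self.root
        while node.attribute is not None:
            node = node.left if x[node.attribute] <= node.threshold else node.right
        return node.label

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return np.array([self.predict_one(x) for x in X])

    def depth(self) -> int:
        def _d(node: _Node) -> int:
            if node.attribute is None:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def to_dict(self) -> dict:
        return {"classes": [str(c) for c in self.classes], "root": self.root.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        return cls(_Node.from_dict(d["root"]), d["classes"])


def _majority_label(y: np.ndarray, w: np.ndarray):
    """Weighted majority; ties break toward the lexicographically smaller label."""
    classes = sorted(set(y.tolist()), key=str)
    weights = [w[y == c].sum() for c in classes]
    return classes[int(np.argmax(weights))], {
        str(c): float(wc / w.sum()) for c, wc in zip(classes, weights)
    }


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    max_depth: int | None = None,
    min_leaf: int = 1,
) -> DecisionTree:
    """Recursive partitioning with gain-ratio splits.

    Recursion stops at node purity, ``max_depth``, ``min_leaf`` (a split that
    would produce a smaller child is rejected) or when no candidate has
    positive gain.  Unlimited depth on consistent data drives training error
    to zero.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training set must be a non-empty 2-D array")
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)

    def build(idx: np.ndarray, depth: int) -> _Node:
        yy, ww = y[idx], w[idx]
        label, probs = _majority_label(yy, ww)
        if len(set(yy.tolist())) == 1 or (max_depth is not None and depth >= max_depth):
            return _Node(label=label, probs=probs)
        cand = best_split(X[idx], yy, ww)
        if cand is None:
            return _Node(label=label, probs=probs)
        go_left = X[idx, cand.attribute] <= cand.threshold
        if go_left.sum() < min_leaf or (~go_left).sum() < min_leaf:
            return _Node(label=label, probs=probs)
        return _Node(
            attribute=cand.attribute,
            threshold=cand.threshold,
            left=build(idx[go_left], depth + 1),
            right=build(idx[~go_left], depth + 1),
        )

    root = build(np.arange(len(y)), 0)
    return DecisionTree(root, sorted(set(y.tolist()), key=str))


@dataclass
class BoostedEnsemble:
    """K (alpha, tree) pairs voting by F(x) = sum_k alpha_k phi_k(x)."""

    members: list  # list[(float alpha, DecisionTree)]
    classes: list
    positive_class: object | None = None  # 2-class: the +1 class (fall)
    feature_names: list | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "positive_class": None
            if self.positive_class is None
            else str(self.positive_class),
            "feature_names": self.feature_names,
            "metadata": self.metadata,
            "members": [
                {"alpha": float(a), "tree": t.to_dict()} for a, t in self.members
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoostedEnsemble":
        return cls(
            members=[(m["alpha"], DecisionTree.from_dict(m["tree"])) for m in d["members"]],
            classes=d["classes"],
            positive_class=d["positive_class"],
            feature_names=d.get("feature_names"),
            metadata=d.get("metadata", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "BoostedEnsemble":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_boosted(
    X: np.ndarray,
    y: np.ndarray,
    K: int = 10,
    base: str = "full_tree",
    max_depth: int | None = None,
    min_leaf: int = 1,
    seed: int = 0,
    feature_names: list | None = None,
) -> BoostedEnsemble:
    """Discrete AdaBoost (SAMME for >2 classes) over gain-ratio trees.

    ``base='full_tree'`` grows unlimited-depth trees (the boosted-J48
    configuration); ``base='stump'`` grows depth-1 stumps (classic AdaBoost).
    Per round: fit on current weights, compute the weighted error eps, stop
    early at eps = 0 (capped to 1e-10 for the vote weight) or
    eps >= 1 - 1/n_classes; otherwise multiply misclassified weights by
    exp(ln((1-eps)/eps) + ln(n_classes-1)) and renormalise.  The stored vote
    weight is alpha = 1/2 ln((1-eps)/eps) for two classes and
    ln((1-eps)/eps) + ln(n_classes-1) otherwise.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if K < 1:
        raise ValueError("K must be >= 1")
    classes = sorted(set(y.tolist()), key=str)
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if base not in ("full_tree", "stump"):
        raise ValueError("base must be 'full_tree' or 'stump'")
    C = len(classes)
    depth = 1 if base == "stump" else max_depth
    n = len(y)
    w = np.full(n, 1.0 / n)
    positive = "fall" if "fall" in classes else classes[0]

    members: list[tuple[float, DecisionTree]] = []
    member_errors: list[float] = []
    for k in range(K):
        tree = grow_tree(X, y, sample_weight=w, max_depth=depth, min_leaf=min_leaf)
        pred = tree.predict(X)
        mis = pred != y
        eps = float(w[mis].sum())
        if eps <= 0.0:
            member_errors.append(eps)
            eps = 1e-10  # perfect learner: cap so alpha stays finite
            members.append((_vote_alpha(eps, C), tree))
            break
        if eps >= 1.0 - 1.0 / C - 1e-12:
            if not members:
                logger.warning(
                    "first base learner no better than chance (eps=%.3f); "
                    "keeping it with a nominal weight",
                    eps,
                )
                members.append((1e-6, tree))
                member_errors.append(eps)
            break
        members.append((_vote_alpha(eps, C), tree))
        member_errors.append(eps)
        reweight = math.log((1.0 - eps) / eps) + (math.log(C - 1) if C > 2 else 0.0)
        w = w * np.exp(reweight * mis)
        w = w / w.sum()

    return BoostedEnsemble(
        members=members,
        classes=classes,
        positive_class=positive if C == 2 else None,
        feature_names=feature_names,
        metadata={"K": K, "base": base, "seed": seed, "member_errors": member_errors},
    )


def _vote_alpha(eps: float, n_classes: int) -> float:
    if n_classes == 2:
        return 0.5 * math.log((1.0 - eps) / eps)
    return math.log((1.0 - eps) / eps) + math.log(n_classes - 1)


def predict(
    ensemble: BoostedEnsemble, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and margins for each row of X.

    Two classes: the margin is the signed vote F(x) with the positive (fall)
    class at +1; the label is its sign, with sign(0) resolved to the positive
    class.  More classes: argmax of per-class alpha-weighted votes, margin =
    winning vote minus runner-up (ties to the lexicographically smaller
    label).
    """
    if not ensemble.members:
        raise ValueError("ensemble has no trained members")
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    classes = list(ensemble.classes)
    if ensemble.n_classes == 2:
        pos = ensemble.positive_class
        neg = next(c for c in classes if c != pos)
        F = np.zeros(n)
        for alpha, tree in ensemble.members:
            pred = tree.predict(X)
            F += alpha * np.where(pred == pos, 1.0, -1.0)
        labels = np.where(F >= 0.0, pos, neg)
        return labels, F
    votes = np.zeros((n, len(classes)))
    for alpha, tree in ensemble.members:
        pred = tree.predict(X)
        for ci, c in enumerate(classes):
            votes[:, ci] += alpha * (pred == c)
    win = np.argmax(votes, axis=1)  # classes are sorted; first max wins ties
    labels = np.array([classes[i] for i in win])
    top = votes[np.arange(n), win]
    votes[np.arange(n), win] = -np.inf
    runner = votes.max(axis=1)
    return labels, top - runner
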