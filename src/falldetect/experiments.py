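"""Canonical desk-scale experiments on the synthetic scenario data.

These functions fix the study conditions — sequence counts, scenario
kinematics (10-frame fall rotation vs. 45-frame sit rotation at 30 fps),
window length k = 30 and 10-fold cross-validation — and are used both by
the acceptance checks and the command line.  Only the master seed varies.
"""

from __future__ import annotations

import numpy as np

from .classify import predict, train_boosted
from .evaluate import MetricsReport, kfold_cv
from .features import FEATURE_NAMES, WindowConfig
from .foreground import SegmentationParams
from .pipeline import dataset_to_feature_table
from .synthetic import ScenarioSpec, generate_dataset

__all__ = [
    "build_feature_dataset",
    "two_class_experiment",
    "three_class_experiment",
    "fall_sit_confusion",
    "boosting_learning_curve",
]

#: two-class run: balanced fall/walk sequences, >= 200 windows per class
TWO_CLASS_MIX = {"fall": 0.5, "walk": 0.5}
TWO_CLASS_N = 12
#: three-class run: fall vs. sitting differ only in rotation speed
THREE_CLASS_MIX = {"fall": 1 / 3, "sit": 1 / 3, "walk": 1 / 3}
THREE_CLASS_N = 12


def build_feature_dataset(
    class_mix: dict[str, float],
    n_sequences: int,
    seed: int,
    spec: ScenarioSpec = ScenarioSpec(),
    params: SegmentationParams = SegmentationParams(),
    window: WindowConfig = WindowConfig(),
):
    """Simulate, segment and extract: pooled (X, y) over all windows."""
    dataset = generate_dataset(n_sequences, class_mix, spec, seed)
    table = dataset_to_feature_table(dataset, params, window)
    X = table[list(FEATURE_NAMES)].to_numpy()
    y = table["label"].to_numpy()
    return X, y, table


def two_class_experiment(seed: int = 1, base: str = "full_tree") -> MetricsReport:
    """Fall vs. walk, 10-fold CV of the boosted gain-ratio tree ensemble."""
    X, y, _ = build_feature_dataset(TWO_CLASS_MIX, TWO_CLASS_N, seed)
    return kfold_cv(X, y, folds=10, seed=seed, base=base, rounds=10)


def three_class_experiment(seed: int = 1, base: str = "full_tree") -> MetricsReport:
    """Fall vs. sitting vs. walk; sitting uses the slow 45-frame rotation."""
    X, y, _ = build_feature_dataset(THREE_CLASS_MIX, THREE_CLASS_N, seed)
    return kfold_cv(X, y, folds=10, seed=seed, base=base, rounds=10)


def fall_sit_confusion(report: MetricsReport) -> float:
    """Fraction of fall/sitting frames confused with each other."""
    classes = [str(c) for c in report.classes]
    i, j = classes.index("fall"), classes.index("sitting")
    m = report.confusion.matrix
    both = m[i].sum() + m[j].sum()
    return float((m[i, j] + m[j, i]) / both)


def boosting_learning_curve(
    seed: int = 1, K: int = 50, base: str = "stump", holdout: float = 0.3
):
    """Train/held-out error of the boosted ensemble as rounds accumulate.

    Returns (train_errors, test_errors, member_errors): per-K ensemble 0-1
    errors on the training split and the held-out split, plus each accepted
    base learner's weighted training error.
    """
    X, y, _ = build_feature_dataset(TWO_CLASS_MIX, TWO_CLASS_N, seed)
    rng = np.random.default_rng(seed)
    n = len(y)
    order = rng.permutation(n)
    n_test = int(round(holdout * n))
    test_idx, train_idx = order[:n_test], order[n_test:]
    Xtr, ytr = X[train_idx], y[train_idx]
    Xte, yte = X[test_idx], y[test_idx]

    ens = train_boosted(Xtr, ytr, K=K, base=base, seed=seed)
    member_errors = list(ens.metadata["member_errors"])

    train_err, test_err = [], []
    for k in range(1, len(ens.members) + 1):
        partial = type(ens)(
            members=ens.members[:k],
            classes=ens.classes,
            positive_class=ens.positive_class,
        )
        ptr, _ = predict(partial, Xtr)
        pte, _ = predict(partial, Xte)
        train_err.append(float(np.mean(ptr != ytr)))
        test_err.append(float(np.mean(pte != yte)))
    return train_err, test_err, member_errors
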