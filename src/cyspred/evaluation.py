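"""k-fold cross-validation and binary performance measures.

Sensitivity, specificity, accuracy and the Matthews correlation
coefficient are all derived from pooled confusion counts:

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    Acc = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

MCC is defined as 0 when any factor under the radical is 0. Fold
results are combined by summing counts before computing the single
estimate (micro-averaging); per-fold reports are returned as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "TP": self.counts.tp,
            "FP": self.counts.fp,
            "TN": self.counts.tn,
            "FN": self.counts.fn,
            "Sn": self.sn,
            "Sp": self.sp,
            "Acc": self.acc,
            "MCC": self.mcc,
        }


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def count_confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Tally TP/FP/TN/FN from +-1 labels and predictions."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == -1) & (p == 1))),
        tn=int(np.sum((y == -1) & (p == -1))),
        fn=int(np.sum((y == 1) & (p == -1))),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sn/Sp/Acc/MCC from confusion counts (see module docstring)."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos == 0:
        raise ValueError("no positive ground-truth samples: Sn undefined")
    if neg == 0:
        raise ValueError("no negative ground-truth samples: Sp undefined")
    sn = counts.tp / pos
    sp = counts.tn / neg
    acc = (counts.tp + counts.tn) / counts.total
    factors = (
        counts.tp + counts.fn,
        counts.tn + counts.fp,
        counts.tp + counts.fp,
        counts.tn + counts.fn,
    )
    if 0 in factors:
        mcc = 0.0
    else:
        mcc = (counts.tp * counts.tn - counts.fn * counts.fp) / math.sqrt(
            math.prod(factors)
        )
    return MetricsReport(sn, sp, acc, mcc, counts)


def make_folds(labels: Sequence[int], cv: CVConfig) -> list[np.ndarray]:
    """Partition sample indices into k folds, reproducibly from the seed.

    Stratified folds keep per-class sizes within one of each other.
    """
    y = np.asarray(labels)
    n = len(y)
    if cv.k > n:
        raise ValueError(f"k={cv.k} exceeds sample count {n}")
    rng = np.random.default_rng(cv.seed)
    folds: list[list[int]] = [[] for _ in range(cv.k)]
    if cv.stratified:
        for cls in sorted(set(y.tolist())):
            idx = np.flatnonzero(y == cls)
            if len(idx) < cv.k:
                raise ValueError(
                    f"class {cls} has {len(idx)} members, fewer than k={cv.k}"
                )
            rng.shuffle(idx)
            for j, i in enumerate(idx):
                folds[j % cv.k].append(int(i))
    else:
        idx = rng.permutation(n)
        for j, i in enumerate(idx):
            folds[j % cv.k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(
    matrix: np.ndarray,
    labels: Sequence[int],
    svm_config,
    cv: CVConfig,
    names: Sequence[str] | None = None,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """k-fold CV with the feature scaler fitted strictly inside each fold.

    Returns the pooled (summed-count) report plus per-fold reports.
    """
    from .model import predict, train_svm

    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    folds = make_folds(y, cv)
    pooled = ConfusionCounts(0, 0, 0, 0)
    fold_reports: list[MetricsReport] = []
    for fold_idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[fold_idx] = False
        model = train_svm(X[mask], y[mask], svm_config, feature_names=names)
        pred, _ = predict(model, X[fold_idx])
        counts = count_confusion(y[fold_idx], pred)
        fold_reports.append(compute_metrics(counts))
        pooled = pooled + counts
    return compute_metrics(pooled), fold_reports


def independent_test(model, matrix: np.ndarray, labels: Sequence[int]) -> MetricsReport:
    """Evaluate a trained model on held-out data."""
    from .model import predict

    X = np.asarray(matrix, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    pred, _ = predict(model, X)
    return compute_metrics(count_confusion(labels, pred))
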