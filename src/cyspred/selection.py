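"""F-score feature statistics and forward selection of physicochemical
properties onto a base feature.

The F-score of one feature column is the squared deviation of the two
class means from the grand mean, divided by the sum of the two
within-class sample variances:

    F = ((m_pos - m)^2 + (m_neg - m)^2) / (var_pos + var_neg)

with variances computed with ddof=1. A zero numerator scores 0; a zero
denominator with nonzero numerator scores +inf (degenerate, sorted
first with a warning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dataset import Fragment
from .encoders import encode_aaindex, encode_matrix
from .evaluation import CVConfig, MetricsReport, cross_validate
from .io_formats import AAIndexEntry
from .model import SVMConfig

logger = logging.getLogger(__name__)


def f_score(values_pos: Sequence[float], values_neg: Sequence[float]) -> float:
    """F-score of one feature from its positive- and negative-class values."""
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("f_score requires at least 2 samples per class")
    grand = np.concatenate([pos, neg]).mean()
    numerator = (pos.mean() - grand) ** 2 + (neg.mean() - grand) ** 2
    if numerator == 0:
        return 0.0
    denominator = pos.var(ddof=1) + neg.var(ddof=1)
    if denominator == 0:
        logger.warning("degenerate F-score: zero within-class variance")
        return float("inf")
    return float(numerator / denominator)


def f_score_columns(matrix_pos: np.ndarray, matrix_neg: np.ndarray) -> np.ndarray:
    """Vectorized per-column F-scores for two class matrices."""
    Xp = np.asarray(matrix_pos, dtype=float)
    Xn = np.asarray(matrix_neg, dtype=float)
    if Xp.shape[0] < 2 or Xn.shape[0] < 2:
        raise ValueError("f_score requires at least 2 samples per class")
    n = Xp.shape[0] + Xn.shape[0]
    grand = (Xp.sum(axis=0) + Xn.sum(axis=0)) / n
    num = (Xp.mean(axis=0) - grand) ** 2 + (Xn.mean(axis=0) - grand) ** 2
    den = Xp.var(axis=0, ddof=1) + Xn.var(axis=0, ddof=1)
    out = np.zeros(Xp.shape[1])
    nonzero_num = num > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    out[nonzero_num & (den > 0)] = ratio[nonzero_num & (den > 0)]
    out[nonzero_num & (den == 0)] = np.inf
    return out


@dataclass(frozen=True)
class FScoreTable:
    """Per-property F-scores, iterable in descending-score order."""

    scores: Mapping[str, float]

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("property\tscore\trank\n")
            for rank, (name, score) in enumerate(self.ranked(), 1):
                fh.write(f"{name}\t{score:.6g}\t{rank}\n")


def score_properties(
    fragments: Sequence[Fragment],
    entries: Sequence[AAIndexEntry],
    normalize: str = "zscore",
) -> FScoreTable:
    """F-score each physicochemical property on labeled fragments.

    Each property is encoded per position; its score is the arithmetic
    mean of the per-position F-scores over the window.
    """
    pos_frags = [f for f in fragments if f.label == 1]
    neg_frags = [f for f in fragments if f.label == -1]
    scores: dict[str, float] = {}
    for entry in entries:
        enc = lambda f: encode_aaindex(f, entry, normalize=normalize)
        Xp, _ = encode_matrix(pos_frags, enc)
        Xn, _ = encode_matrix(neg_frags, enc)
        per_position = f_score_columns(Xp, Xn)
        scores[entry.accession] = float(np.mean(per_position))
        if np.isinf(scores[entry.accession]):
            logger.warning(
                "property %s has degenerate (infinite) F-score", entry.accession
            )
    return FScoreTable(scores)


@dataclass(frozen=True)
class RankedProperty:
    entry: AAIndexEntry
    metrics: MetricsReport


def rank_by_single_accuracy(
    entries: Sequence[AAIndexEntry],
    fragments: Sequence[Fragment],
    svm: SVMConfig,
    cv: CVConfig,
    normalize: str = "zscore",
) -> list[RankedProperty]:
    """Train/evaluate each property alone by k-fold CV; sort by accuracy
    descending, ties broken by MCC then accession."""
    if not entries:
        raise ValueError("no properties to rank")
    labels = np.array([f.label for f in fragments])
    results: list[RankedProperty] = []
    for entry in entries:
        enc = lambda f: encode_aaindex(f, entry, normalize=normalize)
        X, _ = encode_matrix(fragments, enc)
        pooled, _ = cross_validate(X, labels, svm, cv)
        results.append(RankedProperty(entry, pooled))
    results.sort(
        key=lambda r: (-r.metrics.acc, -r.metrics.mcc, r.entry.accession)
    )
    return results


@dataclass(frozen=True)
class SelectionStep:
    feature: str
    metrics: MetricsReport
    accepted: bool


@dataclass
class SelectionTrace:
    """Forward-selection audit trail.

    ``best_prefix`` is the (possibly empty) list of added features whose
    cumulative model maximizes CV MCC; ``best_metrics`` is that model's
    pooled report (the base model's report when the prefix is empty).
    """

    base_metrics: MetricsReport
    steps: list[SelectionStep] = field(default_factory=list)
    best_prefix: list[str] = field(default_factory=list)
    best_metrics: MetricsReport | None = None

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tproperty\taccepted\tSn\tSp\tAcc\tMCC\n")
            m = self.base_metrics
            fh.write(f"0\t<base>\t1\t{m.sn:.4f}\t{m.sp:.4f}\t{m.acc:.4f}\t{m.mcc:.4f}\n")
            for i, s in enumerate(self.steps, 1):
                m = s.metrics
                fh.write(
                    f"{i}\t{s.feature}\t{int(s.accepted)}\t"
                    f"{m.sn:.4f}\t{m.sp:.4f}\t{m.acc:.4f}\t{m.mcc:.4f}\n"
                )


def forward_select(
    base_matrix: np.ndarray,
    candidates: Sequence[tuple[str, np.ndarray]],
    labels: Sequence[int],
    svm: SVMConfig,
    cv: CVConfig,
    mode: str = "cumulative",
) -> SelectionTrace:
    """Add candidate feature blocks to a base matrix in rank order.

    ``cumulative`` mode keeps every tried candidate (the curve
    semantics); ``greedy`` retains a candidate only when it improves the
    pooled CV MCC. In both modes the returned best prefix is the one
    maximizing MCC, so its score is never below the base model's.
    """
    if mode not in ("cumulative", "greedy"):
        raise ValueError(f"unknown mode {mode!r}")
    if not candidates:
        raise ValueError("candidates must be non-empty")
    y = np.asarray(labels)
    base_metrics, _ = cross_validate(base_matrix, y, svm, cv)
    trace = SelectionTrace(base_metrics=base_metrics)
    current = np.asarray(base_matrix, dtype=float)
    accepted: list[str] = []
    best_mcc = base_metrics.mcc
    best_prefix: list[str] = []
    best_metrics = base_metrics
    for name, block in candidates:
        trial = np.hstack([current, np.asarray(block, dtype=float)])
        pooled, _ = cross_validate(trial, y, svm, cv)
        if mode == "cumulative":
            keep = True
        else:
            keep = pooled.mcc > best_mcc
        trace.steps.append(SelectionStep(name, pooled, keep))
        if keep:
            current = trial
            accepted.append(name)
            if pooled.mcc > best_mcc:
                best_mcc = pooled.mcc
                best_prefix = list(accepted)
                best_metrics = pooled
    trace.best_prefix = best_prefix
    trace.best_metrics = best_metrics
    return trace
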