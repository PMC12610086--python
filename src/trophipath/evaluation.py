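"""Detection/segmentation evaluation metrics and confusion aggregation.

Covers the standard binary-detection bookkeeping for mitotic-figure
pipelines: per-negative-class confusion rows (each hard-negative class —
ink, anthracosis, muscle/fibroblast nuclei, necrotic chromatin — is
evaluated against the same positive set), their combination into one
row, sensitivity/specificity/precision/F1, mask-overlap IoU/Dice for
interobserver agreement, ROC-AUC, and the two-stage
detection/classification threshold sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import ParameterError, UndefinedMetricError, ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN for one negative class (or a combined row)."""

    tp: int
    fp: int
    tn: int
    fn: int
    negative_class: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricSet:
    """Threshold-level classification metrics derived from counts."""

    sensitivity: float
    specificity: float
    precision: float
    f1: float


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding used in reports (0.965 -> 0.97)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def confusion_metrics(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, precision and F1 from one confusion row."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: tp+fn=0")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: tn+fp=0")
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: tp+fp=0")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    prec = c.tp / (c.tp + c.fp)
    f1 = 0.0 if prec + sens == 0 else 2 * prec * sens / (prec + sens)
    return MetricSet(sensitivity=sens, specificity=spec, precision=prec, f1=f1)


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall <= 0:
        raise UndefinedMetricError("F1 undefined: precision + recall = 0")
    return 2 * precision * recall / (precision + recall)


def fbeta_from_pr(precision: float, recall: float, beta: float = 1.0) -> float:
    """General F-beta score (beta weighs recall over precision)."""
    if beta <= 0:
        raise ParameterError("beta must be positive")
    denom = beta**2 * precision + recall
    if denom <= 0:
        raise UndefinedMetricError("F-beta undefined: zero denominator")
    return (1 + beta**2) * precision * recall / denom


def combine_negative_classes(rows: Sequence[ConfusionCounts]) -> ConfusionCounts:
    """Merge per-negative-class rows sharing one positive set.

    All rows must carry identical tp and fn (they evaluate the same
    positives); fp and tn sum across rows.
    """
    if not rows:
        raise ValidationError("no confusion rows to combine")
    tp, fn = rows[0].tp, rows[0].fn
    for r in rows[1:]:
        if r.tp != tp or r.fn != fn:
            raise ValidationError(
                "cannot combine rows with differing tp/fn (different positive sets)"
            )
    return ConfusionCounts(
        tp=tp,
        fp=sum(r.fp for r in rows),
        tn=sum(r.tn for r in rows),
        fn=fn,
        negative_class="+".join(r.negative_class for r in rows) or "combined",
    )


def overlap_metrics(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """IoU and Dice of two boolean masks of identical shape.

    Two empty masks agree perfectly: both metrics are defined as 1.0
    (the interobserver-agreement convention).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0, 1.0
    iou = inter / union
    dice = 2 * inter / (a.sum() + b.sum())
    return float(iou), float(dice)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve (trapezoidal; ties rank-averaged)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValidationError("ROC-AUC needs both label classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def threshold_sweep(
    scores: Sequence[tuple[float, float]],
    labels: Sequence[bool],
    detection_thr: float,
    classification_thr: float,
) -> ConfusionCounts:
    """Two-stage counting: detection gate then classification gate.

    ``scores`` holds (detection_score, classification_score) per
    candidate.  A candidate is called positive iff its detection score
    reaches ``detection_thr`` and its classification score reaches
    ``classification_thr``; counts follow from the boolean labels.
    """
    if not (0.0 <= detection_thr <= 1.0 and 0.0 <= classification_thr <= 1.0):
        raise ParameterError("thresholds must lie in [0, 1]")
    arr = np.asarray(scores, dtype=float).reshape(-1, 2)
    lab = np.asarray(labels, dtype=bool)
    if len(arr) != len(lab):
        raise ValidationError("scores and labels length mismatch")
    called = (arr[:, 0] >= detection_thr) & (arr[:, 1] >= classification_thr)
    return ConfusionCounts(
        tp=int(np.sum(called & lab)),
        fp=int(np.sum(called & ~lab)),
        tn=int(np.sum(~called & ~lab)),
        fn=int(np.sum(~called & lab)),
    )


# ---------------------------------------------------------------------------
# CSV interchange for confusion tables

_CSV_COLUMNS = ["negative_class", "tp", "fp", "tn", "fn"]


def read_confusion_csv(path: str | Path) -> list[ConfusionCounts]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"confusion CSV missing columns: {sorted(missing)}")
    return [
        ConfusionCounts(tp=int(r.tp), fp=int(r.fp), tn=int(r.tn), fn=int(r.fn),
                        negative_class=str(r.negative_class))
        for r in df.itertuples()
    ]


def write_confusion_csv(rows: Sequence[ConfusionCounts], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"negative_class": r.negative_class, "tp": r.tp, "fp": r.fp,
             "tn": r.tn, "fn": r.fn}
            for r in rows
        ],
        columns=_CSV_COLUMNS,
    ).to_csv(path, index=False)


__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion_metrics",
    "f1_from_pr",
    "fbeta_from_pr",
    "combine_negative_classes",
    "overlap_metrics",
    "roc_auc",
    "threshold_sweep",
    "round_half_up",
    "read_confusion_csv",
    "write_confusion_csv",
]
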