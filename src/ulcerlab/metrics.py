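"""Pixel-level segmentation metrics: Dice, IoU, precision, recall, accuracy.

All five metrics derive from per-pixel confusion counts.  Dice (the F1
score) is 2TP/(2TP+FP+FN); IoU is TP/(TP+FP+FN); the two are linked by
dice = 2*iou/(1+iou).  The Dice loss 1 - (2TP+eps)/(2TP+FP+FN+eps)
regularizes the empty-vs-empty case with a small eps.  Undefined ratios
(zero denominator) are reported as NaN, never silently as 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "MetricsReport",
    "confusion",
    "dice",
    "iou",
    "precision",
    "recall",
    "accuracy",
    "dice_loss",
    "evaluate",
]

DEFAULT_EPS = 1e-6


class ConfusionCounts(NamedTuple):
    """Per-pixel confusion counts for one binary class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":  # type: ignore[override]
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exhaustive per-pixel confusion counts of two binary masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def dice(c: ConfusionCounts) -> float:
    """Dice coefficient 2TP/(2TP+FP+FN); both-empty counts as agreement."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("dice of two empty masks: returning 1.0 (perfect agreement)")
        return 1.0
    return 2 * c.tp / denom


def iou(c: ConfusionCounts) -> float:
    """Intersection over union TP/(TP+FP+FN); NaN when undefined."""
    denom = c.tp + c.fp + c.fn
    return c.tp / denom if denom else float("nan")


def precision(c: ConfusionCounts) -> float:
    """Positive predictive value TP/(TP+FP); NaN when nothing predicted."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else float("nan")


def recall(c: ConfusionCounts) -> float:
    """Sensitivity TP/(TP+FN); NaN when the truth is empty."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else float("nan")


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of correctly classified pixels."""
    return (c.tp + c.tn) / c.total if c.total else float("nan")


def dice_loss(c: ConfusionCounts, eps: float = DEFAULT_EPS) -> float:
    """Dice loss 1 - (2TP+eps)/(2TP+FP+FN+eps); eps guards the 0/0 case."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    return 1.0 - (2 * c.tp + eps) / (2 * c.tp + c.fp + c.fn + eps)


@dataclass
class ClassMetrics:
    """The five metrics plus Dice loss for one binary class."""

    counts: ConfusionCounts
    dice: float
    iou: float
    precision: float
    recall: float
    accuracy: float
    dice_loss: float

    @classmethod
    def from_counts(cls, c: ConfusionCounts, eps: float = DEFAULT_EPS) -> "ClassMetrics":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = dice(c)
        return cls(
            counts=c, dice=d, iou=iou(c), precision=precision(c), recall=recall(c),
            accuracy=accuracy(c), dice_loss=dice_loss(c, eps),
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp, "fp": self.counts.fp,
            "tn": self.counts.tn, "fn": self.counts.fn,
            "dice": self.dice, "iou": self.iou, "precision": self.precision,
            "recall": self.recall, "accuracy": self.accuracy,
            "dice_loss": self.dice_loss,
        }


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics with micro and macro aggregates.

    Micro pools the confusion counts over classes before computing each
    metric; macro averages the per-class metric values (NaN-aware).
    """

    per_class: dict[str, ClassMetrics]
    micro: ClassMetrics
    macro: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "per_class": {k: v.to_dict() for k, v in self.per_class.items()},
            "micro": self.micro.to_dict(),
            "macro": self.macro,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_frame(self) -> pd.DataFrame:
        rows = {k: v.to_dict() for k, v in self.per_class.items()}
        rows["micro"] = self.micro.to_dict()
        rows["macro"] = self.macro
        return pd.DataFrame(rows).T

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def evaluate(
    pred: np.ndarray,
    truth: np.ndarray,
    classes: Sequence,
    eps: float = DEFAULT_EPS,
) -> MetricsReport:
    """Evaluate categorical label maps class-by-class (one-vs-rest).

    ``classes`` names the label vocabulary: index i in the maps means
    ``classes[i]``.  Background (index 0) is included in the per-class
    table like any other class but conventionally read separately.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    ncls = len(classes)
    if int(pred.max(initial=0)) >= ncls or int(truth.max(initial=0)) >= ncls:
        raise ValueError("label maps contain indices outside the class vocabulary")
    per_class: dict[str, ClassMetrics] = {}
    pooled = ConfusionCounts(0, 0, 0, 0)
    for i, cls in enumerate(classes):
        name = getattr(cls, "value", str(cls))
        c = confusion(pred == i, truth == i)
        per_class[name] = ClassMetrics.from_counts(c, eps)
        pooled = pooled + c
    micro = ClassMetrics.from_counts(pooled, eps)
    metric_names = ("dice", "iou", "precision", "recall", "accuracy", "dice_loss")
    macro = {
        name: float(np.nanmean([getattr(m, name) for m in per_class.values()]))
        for name in metric_names
    }
    return MetricsReport(per_class=per_class, micro=micro, macro=macro)
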