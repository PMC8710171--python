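"""Segmentation metrics: confusion matrix, per-class and aggregate scores.

Per class c (one-vs-rest pixel sets): recall TP/(TP+FN), precision
TP/(TP+FP), F1 = 2PR/(P+R), Dice = 2TP/(2TP+FP+FN) (algebraically equal to
F1), IoU = TP/(TP+FP+FN).  Aggregates are unweighted means over the
*foreground* classes only — background dominates medical label maps and
would inflate every score — while overall pixel accuracy (trace/total,
background included) and mean foreground recall are reported separately
under explicit names, since "accuracy" is ambiguous between the two.

Empty-class convention: a class absent from both truth and prediction
scores 1.0 (nothing to get wrong); absent from truth but predicted scores
0.0 (pure false positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = ["ConfusionMatrix", "MetricsReport", "label_map_from_probs",
           "confusion_matrix", "per_class_metrics", "aggregate_report",
           "evaluate_predictions"]

METRIC_NAMES = ("recall", "precision", "f1", "dice", "iou")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K); rows = truth, cols = prediction

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        """Row-normalised matrix in percent (rows sum to 100)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        sums[sums == 0] = 1.0
        return 100.0 * self.counts / sums

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass
class MetricsReport:
    per_class: dict[int, dict[str, float]]
    mean_foreground: dict[str, float]
    pixel_accuracy: float          # trace / total, background included
    mean_foreground_recall: float  # mean of foreground diagonal rates
    confusion: ConfusionMatrix = field(repr=False, default=None)

    @property
    def mean_foreground_dice(self) -> float:
        return self.mean_foreground["dice"]

    def summary(self) -> str:
        lines = ["class  recall  precision  f1      dice    iou"]
        for c, row in sorted(self.per_class.items()):
            lines.append(
                f"{c:>5}  " + "  ".join(f"{row[m]:.4f}" for m in METRIC_NAMES))
        agg = self.mean_foreground
        lines.append(
            " fg-mean  " + "  ".join(f"{agg[m]:.4f}" for m in METRIC_NAMES))
        lines.append(f"pixel accuracy (incl. background): "
                     f"{self.pixel_accuracy:.4f}")
        lines.append(f"mean foreground recall: "
                     f"{self.mean_foreground_recall:.4f}")
        return "\n".join(lines)


def label_map_from_probs(p: np.ndarray) -> np.ndarray:
    """Per-pixel argmax of a (K, H, W) probability map; ties go to the
    lowest class index (numpy argmax convention)."""
    p = np.asarray(p)
    if p.ndim != 3:
        raise ValueError(f"expected (K, H, W) probability map, got {p.shape}")
    return p.argmax(axis=0)


def confusion_matrix(pred: np.ndarray, truth: np.ndarray,
                     num_classes: int) -> ConfusionMatrix:
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    for name, arr in (("pred", pred), ("truth", truth)):
        if arr.min() < 0 or arr.max() >= num_classes:
            raise ValueError(f"{name} labels outside [0, {num_classes})")
    counts = _sk_confusion(truth, pred, labels=np.arange(num_classes))
    return ConfusionMatrix(counts.astype(np.int64))


def per_class_metrics(cm: ConfusionMatrix) -> dict[int, dict[str, float]]:
    counts = cm.counts
    k = cm.num_classes
    rows: dict[int, dict[str, float]] = {}
    for c in range(k):
        tp = float(counts[c, c])
        fn = float(counts[c].sum() - tp)
        fp = float(counts[:, c].sum() - tp)
        if tp + fn + fp == 0:       # absent everywhere
            vals = dict.fromkeys(METRIC_NAMES, 1.0)
        elif tp + fn == 0:          # never true, but predicted
            vals = dict.fromkeys(METRIC_NAMES, 0.0)
        else:
            recall = tp / (tp + fn)
            precision = tp / (tp + fp) if tp + fp > 0 else 0.0
            f1 = (2 * precision * recall / (precision + recall)
                  if precision + recall > 0 else 0.0)
            dice = 2 * tp / (2 * tp + fp + fn)
            iou = tp / (tp + fp + fn)
            vals = {"recall": recall, "precision": precision, "f1": f1,
                    "dice": dice, "iou": iou}
        rows[c] = vals
    return rows


def aggregate_report(cm: ConfusionMatrix,
                     exclude_background: bool = True) -> MetricsReport:
    rows = per_class_metrics(cm)
    classes = [c for c in rows if c != 0] if exclude_background else list(rows)
    mean_fg = {m: float(np.mean([rows[c][m] for c in classes]))
               for m in METRIC_NAMES}
    total = cm.total
    acc = float(np.trace(cm.counts)) / total if total else 1.0
    fg_recall = float(np.mean([rows[c]["recall"] for c in classes]))
    return MetricsReport(per_class=rows, mean_foreground=mean_fg,
                         pixel_accuracy=acc,
                         mean_foreground_recall=fg_recall, confusion=cm)


def evaluate_predictions(preds, truths, num_classes: int) -> MetricsReport:
    """Pool pixel counts over paired (H, W) label-map sequences."""
    cm = ConfusionMatrix(np.zeros((num_classes, num_classes), dtype=np.int64))
    for p, t in zip(preds, truths):
        cm = cm + confusion_matrix(p, t, num_classes)
    return aggregate_report(cm)
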