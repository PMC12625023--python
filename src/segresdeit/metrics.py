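"""Confusion-count algebra, classification/segmentation metrics and ROC.

Every reported metric derives from the TP/TN/FP/FN quadruple:

  accuracy  = (TP+TN) / (TP+TN+FP+FN)
  precision = TP / (TP+FP)
  recall    = TP / (TP+FN)
  F1        = harmonic mean of precision and recall = 2TP / (2TP+FP+FN)
  Dice      = 2TP / (2TP+FP+FN)      (== F1 on binary counts)
  IoU       = TP / (TP+FP+FN)        (Dice = 2*IoU / (1+IoU))

A zero denominator yields 0 with a warning.  Display rounding is 4 decimals,
half-up.  ROC/AUC follows the usual threshold sweep over unique scores with
trapezoidal integration (delegated to scikit-learn).
"""

from __future__ import annotations

import csv
import decimal
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve

from .architecture import SegResDeiT
from .data_pipeline import ImageMaskPair
from .tensor import Tensor


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    dice: float
    iou: float
    auc: Optional[float] = None

    @classmethod
    def from_counts(cls, c: ConfusionCounts, auc: Optional[float] = None) -> "MetricReport":
        return cls(
            accuracy=accuracy(c), precision=precision(c), recall=recall(c),
            f1=f1(c), dice=dice(c), iou=iou(c), auc=auc,
        )

    def rounded(self, digits: int = 4) -> dict[str, Optional[float]]:
        """Half-up rounding for display, matching the reporting convention."""
        out = {}
        for key, value in asdict(self).items():
            if value is None:
                out[key] = None
            else:
                q = decimal.Decimal(10) ** -digits
                out[key] = float(
                    decimal.Decimal(repr(value)).quantize(
                        q, rounding=decimal.ROUND_HALF_UP
                    )
                )
        return out


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, returning 0 by convention")
        return 0.0
    return num / den


def count_confusion(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must share shape")
    for arr, name in ((predicted, "predicted"), (truth, "truth")):
        if not np.isin(np.unique(arr), (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    p = predicted.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def accuracy(c: ConfusionCounts) -> float:
    return _safe_div(c.tp + c.tn, c.total, "accuracy")


def precision(c: ConfusionCounts) -> float:
    return _safe_div(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _safe_div(c.tp, c.tp + c.fn, "recall")


def f1(c: ConfusionCounts) -> float:
    return _safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1")


def dice(c: ConfusionCounts) -> float:
    return _safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn, "dice")


def iou(c: ConfusionCounts) -> float:
    return _safe_div(c.tp, c.tp + c.fp + c.fn, "iou")


def roc_curve(scores: Sequence[float], labels: Sequence[int]):
    """Threshold-swept ROC with trapezoidal AUC; ties grouped by score.

    Raises on single-class label vectors (the curve is undefined).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

MASK_THRESHOLD = 0.5
CLASS_THRESHOLD = 0.5


def evaluate_model(
    model: SegResDeiT,
    dataset: Sequence[ImageMaskPair],
    mode: str = "image",
    batch_size: int = 8,
) -> MetricReport:
    """Evaluate a model on a dataset in `pixel` or `image` mode.

    * pixel mode — confusion tabulated over every mask pixel at threshold
      0.5; AUC over pixel probabilities when both pixel classes occur.
    * image mode — confusion over thresholded image-level predictions; AUC
      over class probabilities when both labels occur.
    """
    if mode not in ("pixel", "image"):
        raise ValueError("mode must be 'pixel' or 'image'")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    model.eval()
    mask_probs, class_probs = [], []
    for start in range(0, len(dataset), batch_size):
        chunk = dataset[start : start + batch_size]
        x = Tensor(np.stack([p.image.transpose(2, 0, 1) for p in chunk]))
        out = model(x)
        mask_probs.append(out.mask_probability.data[:, 0])
        class_probs.append(out.class_probability.data)
    mask_prob = np.concatenate(mask_probs)
    class_prob = np.concatenate(class_probs)
    masks = np.stack([p.mask for p in dataset])
    labels = np.array([p.label for p in dataset])

    if mode == "pixel":
        pred = (mask_prob >= MASK_THRESHOLD).astype(np.uint8)
        counts = count_confusion(pred, masks)
        auc_val = None
        if np.unique(masks).size == 2:
            _, _, auc_val = roc_curve(mask_prob.ravel(), masks.ravel())
    else:
        pred = (class_prob >= CLASS_THRESHOLD).astype(np.uint8)
        counts = count_confusion(pred, labels)
        auc_val = None
        if np.unique(labels).size == 2:
            _, _, auc_val = roc_curve(class_prob, labels)
    return MetricReport.from_counts(counts, auc=auc_val)


# ---------------------------------------------------------------------------
# published confusion counts (test-set, image-level) used as metric inputs
# ---------------------------------------------------------------------------

PUBLISHED_COUNTS: dict[str, ConfusionCounts] = {
    "SegResDeiT": ConfusionCounts(tp=903, tn=361, fp=41, fn=33),
    "Swin-UNet": ConfusionCounts(tp=828, tn=320, fp=82, fn=108),
    "nnU-Net": ConfusionCounts(tp=770, tn=290, fp=112, fn=166),
    "DeepLabV3+ (ResNet-50)": ConfusionCounts(tp=754, tn=280, fp=122, fn=182),
}


def metrics_from_counts_table(
    rows: Iterable[dict],
) -> list[dict]:
    """Compute a metric table from rows of {model, tp, tn, fp, fn}."""
    out = []
    for row in rows:
        c = ConfusionCounts(
            tp=int(row["tp"]), tn=int(row["tn"]), fp=int(row["fp"]), fn=int(row["fn"])
        )
        rec = {"model": row["model"]}
        rec.update(MetricReport.from_counts(c).rounded())
        rec.pop("auc")
        out.append(rec)
    return out


def write_metrics_csv(path: str | Path, rows: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
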