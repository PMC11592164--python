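"""Classification and segmentation evaluation under support-weighted conventions.

Classification is scored from a 2x2 confusion matrix with melanoma as the
positive class. Because dermoscopy test sets are imbalanced, the headline
measures are support-weighted: the weighted TPR is the support-weighted mean
of per-class recalls (algebraically equal to overall accuracy), the weighted
F1 is the support-weighted mean of per-class F1 scores, TNR is the benign
class recall (i.e. specificity for melanoma), and melanoma recall is the
sensitivity. Percentages are reported on a 0-100 scale; ``round_half_up``
matches conventional half-up rounding at a printed precision.

Segmentation is scored per image from pixel counts (lesion = positive):
DSC = 2TP/(2TP+FP+FN), IOU = TP/(TP+FP+FN), and the Matthews correlation
coefficient. Dataset scores are unweighted means over test images.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .io_prep import ImageSample


class UndefinedMetricError(ValueError):
    """Raised when a metric's support is empty."""


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (printed convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# -- classification --------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts of true class (rows) vs predicted class (columns).

    ``bb``: benign predicted benign; ``bm``: benign predicted melanoma;
    ``mb``: melanoma predicted benign; ``mm``: melanoma predicted melanoma.
    """

    bb: int
    bm: int
    mb: int
    mm: int

    def __post_init__(self):
        if min(self.bb, self.bm, self.mb, self.mm) < 0:
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def n(self) -> int:
        return self.bb + self.bm + self.mb + self.mm

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix2x2":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            bb=int(((y_true == 0) & (y_pred == 0)).sum()),
            bm=int(((y_true == 0) & (y_pred == 1)).sum()),
            mb=int(((y_true == 1) & (y_pred == 0)).sum()),
            mm=int(((y_true == 1) & (y_pred == 1)).sum()),
        )

    def as_dict(self) -> dict:
        return {"bb": self.bb, "bm": self.bm, "mb": self.mb, "mm": self.mm}


def melanoma_recall(cm: ConfusionMatrix2x2) -> float:
    """Sensitivity (TPR) for the melanoma class, in percent."""
    support = cm.mm + cm.mb
    if support == 0:
        raise UndefinedMetricError("no melanoma samples in the confusion matrix")
    return 100.0 * cm.mm / support


def tnr_benign(cm: ConfusionMatrix2x2) -> float:
    """Benign-class recall (specificity for melanoma), in percent."""
    support = cm.bb + cm.bm
    if support == 0:
        raise UndefinedMetricError("no benign samples in the confusion matrix")
    return 100.0 * cm.bb / support


def weighted_tpr(cm: ConfusionMatrix2x2) -> float:
    """Support-weighted mean of per-class recalls = overall accuracy, percent."""
    if cm.bb + cm.bm == 0 or cm.mm + cm.mb == 0:
        raise UndefinedMetricError("both class supports must be positive")
    return 100.0 * (cm.bb + cm.mm) / cm.n


def weighted_f1(cm: ConfusionMatrix2x2) -> float:
    """Support-weighted mean of per-class F1 scores, in percent.

    A class whose precision is undefined (no predictions of that class)
    contributes an F1 of 0.
    """
    if cm.bb + cm.bm == 0 or cm.mm + cm.mb == 0:
        raise UndefinedMetricError("both class supports must be positive")

    def f1(tp, fp, fn):
        denom = 2 * tp + fp + fn
        return 2.0 * tp / denom if denom else 0.0

    f1_b = f1(cm.bb, cm.mb, cm.bm)
    f1_m = f1(cm.mm, cm.bm, cm.mb)
    sup_b, sup_m = cm.bb + cm.bm, cm.mm + cm.mb
    return 100.0 * (sup_b * f1_b + sup_m * f1_m) / cm.n


def classification_summary(cm: ConfusionMatrix2x2) -> dict:
    return {
        "weighted_tpr": weighted_tpr(cm),
        "tnr": tnr_benign(cm),
        "melanoma_recall": melanoma_recall(cm),
        "weighted_f1": weighted_f1(cm),
        "confusion_matrix": cm.as_dict(),
    }


# -- segmentation ----------------------------------------------------------


@dataclass(frozen=True)
class SegPixelCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_masks(cls, pred: np.ndarray, truth: np.ndarray) -> "SegPixelCounts":
        pred = np.asarray(pred).astype(bool)
        truth = np.asarray(truth).astype(bool)
        if pred.shape != truth.shape:
            raise ValueError("prediction and ground truth shapes differ")
        return cls(
            tp=int((pred & truth).sum()),
            fp=int((pred & ~truth).sum()),
            tn=int((~pred & ~truth).sum()),
            fn=int((~pred & truth).sum()),
        )


def dsc(c: SegPixelCounts) -> float:
    """Dice similarity coefficient; empty-vs-empty masks score 1."""
    denom = 2 * c.tp + c.fp + c.fn
    return 2.0 * c.tp / denom if denom else 1.0


def iou(c: SegPixelCounts) -> float:
    """Jaccard index; empty-vs-empty masks score 1."""
    denom = c.tp + c.fp + c.fn
    return c.tp / denom if denom else 1.0


def mcc(c: SegPixelCounts) -> float:
    """Matthews correlation coefficient over pixels; 0 when degenerate."""
    denom = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0.0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / denom


# -- dataset evaluation ----------------------------------------------------


@dataclass
class MetricReport:
    per_image: pd.DataFrame  # columns: id, dsc, iou, mcc
    mean_dsc: float
    mean_iou: float
    mean_mcc: float
    confusion: ConfusionMatrix2x2 | None

    @property
    def weighted_f1(self) -> float:
        return weighted_f1(self.confusion)

    def classification(self) -> dict:
        return classification_summary(self.confusion) if self.confusion else {}


def evaluate_outputs(
    pred_masks: dict[str, np.ndarray],
    pred_labels: dict[str, int] | None,
    samples: list[ImageSample],
) -> MetricReport:
    """Score predictions against ground truth for a list of samples.

    ``pred_masks`` maps sample id -> binary mask; ``pred_labels`` maps id ->
    0/1 class (``None`` for segmentation-only evaluation).
    """
    rows = []
    y_true, y_pred = [], []
    for s in samples:
        if s.id not in pred_masks:
            raise KeyError(f"missing prediction for sample {s.id!r}")
        counts = SegPixelCounts.from_masks(pred_masks[s.id], s.mask)
        rows.append({"id": s.id, "dsc": dsc(counts), "iou": iou(counts), "mcc": mcc(counts)})
        if pred_labels is not None:
            if s.id not in pred_labels:
                raise KeyError(f"missing class prediction for sample {s.id!r}")
            y_true.append(s.label)
            y_pred.append(pred_labels[s.id])
    df = pd.DataFrame(rows)
    cm = ConfusionMatrix2x2.from_predictions(y_true, y_pred) if pred_labels is not None else None
    return MetricReport(
        per_image=df,
        mean_dsc=float(df["dsc"].mean()),
        mean_iou=float(df["iou"].mean()),
        mean_mcc=float(df["mcc"].mean()),
        confusion=cm,
    )


def evaluate_model(
    model, samples: list[ImageSample], batch_size: int = 10
) -> MetricReport:
    """Run the model over samples (masks binarized at 0.5, classes at 0.5)."""
    from .training import samples_to_arrays

    model.eval()
    x, _, _ = samples_to_arrays(samples)
    pred_masks: dict[str, np.ndarray] = {}
    pred_labels: dict[str, int] | None = {} if model.cfg.cls_enabled else None
    for i in range(0, len(samples), batch_size):
        batch = samples[i : i + batch_size]
        masks, probs = model.predict(x[i : i + len(batch)])
        for j, s in enumerate(batch):
            pred_masks[s.id] = masks[j]
            if pred_labels is not None:
                pred_labels[s.id] = int(probs[j] >= 0.5)
    return evaluate_outputs(pred_masks, pred_labels, samples)


def write_report(report: MetricReport, out_dir) -> None:
    """Export metrics.json, per_image_metrics.csv, confusion_matrix.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {
        "mean_dsc": report.mean_dsc,
        "mean_iou": report.mean_iou,
        "mean_mcc": report.mean_mcc,
    }
    if report.confusion is not None:
        summary.update(report.classification())
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    report.per_image.to_csv(out_dir / "per_image_metrics.csv", index=False)
    if report.confusion is not None:
        with open(out_dir / "confusion_matrix.json", "w") as fh:
            json.dump(report.confusion.as_dict(), fh, indent=2)
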