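"""Classification and segmentation evaluation.

Classification metrics use carcinoma as the positive class:

    Acc = (TP+TN)/(TP+FP+TN+FN),  Se = TP/(TP+FN),  Sp = TN/(TN+FP),
    Pr = TP/(TP+FP),              F1 = 2·TP/(2·TP+FP+FN),

reported as percentages rounded half-up to two decimals. Segmentation
quality between a predicted mask X and ground truth Y is measured by the
Dice coefficient D = 2|X∩Y|/(|X|+|Y|) and the Hausdorff distance
H(X,Y) = max(h(X,Y), h(Y,X)) over foreground pixel coordinates with
Euclidean distance. Because classification datasets rarely ship nucleus
annotations, a pseudo ground truth can be produced by binarizing every
image with one shared global threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.spatial.distance import directed_hausdorff
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classify import CARCINOMA, NON_CARCINOMA
from .exceptions import DimensionError
from .segmentation import rgb_to_gray

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
    "dice",
    "hausdorff",
    "pseudo_ground_truth",
    "dice_aggregate",
]


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN with carcinoma as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """The five metrics as percentages (None where undefined)."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally the confusion counts of binary carcinoma predictions."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise DimensionError("label lists have different lengths")
    valid = {CARCINOMA, NON_CARCINOMA}
    counts = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for t, p in zip(y_true, y_pred):
        if t not in valid or p not in valid:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        if t == CARCINOMA:
            counts["tp" if p == CARCINOMA else "fn"] += 1
        else:
            counts["tn" if p == NON_CARCINOMA else "fp"] += 1
    return ConfusionCounts(**counts)


def _pct(numer: float, denom: float) -> float | None:
    """Percentage rounded half-up to 2 decimals; None if undefined."""
    if denom == 0:
        return None
    value = Decimal(numer) / Decimal(denom) * 100
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and F1 from counts."""
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    return MetricsReport(
        accuracy=_pct(c.tp + c.tn, c.total),
        sensitivity=_pct(c.tp, c.tp + c.fn),
        specificity=_pct(c.tn, c.tn + c.fp),
        precision=_pct(c.tp, c.tp + c.fp),
        f1=_pct(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def roc_auc(scores, labels):
    """ROC curve and AUC with carcinoma as the positive class.

    Returns ``((fpr, tpr, thresholds), auc)``; equal scores are grouped
    into a single operating point and the area is the trapezoid rule.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    y = labels == CARCINOMA
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(y, scores)
    return (fpr, tpr, thresholds), float(_sk_auc(fpr, tpr))


def dice(X: np.ndarray, Y: np.ndarray) -> float:
    """Dice coefficient 2|X∩Y|/(|X|+|Y|); two empty masks agree (D=1)."""
    X = np.asarray(X).astype(bool)
    Y = np.asarray(Y).astype(bool)
    if X.shape != Y.shape:
        raise DimensionError(f"mask shapes differ: {X.shape} vs {Y.shape}")
    size = int(X.sum()) + int(Y.sum())
    if size == 0:
        return 1.0
    return 2.0 * int((X & Y).sum()) / size


def hausdorff(X: np.ndarray, Y: np.ndarray) -> float:
    """Symmetric Hausdorff distance between foreground pixel sets."""
    X = np.asarray(X).astype(bool)
    Y = np.asarray(Y).astype(bool)
    if X.shape != Y.shape:
        raise DimensionError(f"mask shapes differ: {X.shape} vs {Y.shape}")
    px, py = np.argwhere(X), np.argwhere(Y)
    if len(px) == 0 or len(py) == 0:
        raise ValueError("Hausdorff distance requires nonempty masks")
    return max(directed_hausdorff(px, py)[0], directed_hausdorff(py, px)[0])


def pseudo_ground_truth(img: np.ndarray, threshold: float) -> np.ndarray:
    """Fixed-threshold binarization used as a surrogate ground truth.

    Pixels darker than ``threshold`` (nuclei under H&E) become
    foreground. The same threshold value must be shared by every image of
    a run; callers typically derive it once (e.g. the Otsu threshold of
    the first image) and pass it unchanged.
    """
    img = np.asarray(img)
    gray = rgb_to_gray(img) if img.ndim == 3 else img.astype(np.float64)
    return (gray < threshold).astype(np.uint8)


def dice_aggregate(per_image):
    """Aggregate per-image Dice scores: overall mean + per-category max."""
    per_image = list(per_image)
    if not per_image:
        raise ValueError("no Dice scores to aggregate")
    values = [d for d, _ in per_image]
    by_cat: dict = {}
    for d, cat in per_image:
        by_cat[cat] = max(by_cat.get(cat, 0.0), d)
    return float(np.mean(values)), by_cat
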