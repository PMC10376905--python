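"""Binary-classification evaluation: confusion matrix, derived metrics,
agreement statistics, ROC/AUC and the five-tier probability bands.

Conventions: the positive class is "pathogenic" (label 1).  Confusion
matrices are reported in rows-are-predicted orientation.  Metrics with
an undefined (zero) denominator are returned as 0.0 with a warning, and
MCC defaults to 0 when any marginal is empty.  All rates are fractions
in [0, 1]; rendering helpers format them as percentages at two decimals.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RocCurve",
    "TIER_LABELS",
    "confusion_counts",
    "classification_metrics",
    "matthews_cc",
    "cohen_kappa",
    "interpret_kappa",
    "roc_auc",
    "assign_tier",
]


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_predicted_rows(self) -> str:
        """Render in rows-are-predicted orientation."""
        return ("            actual-benign  actual-pathogenic\n"
                f"pred-benign   {self.tn:>10d}  {self.fn:>15d}\n"
                f"pred-path.    {self.fp:>10d}  {self.tp:>15d}")


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    error_rate: float
    mcc: float
    f1: float
    kappa: float
    n: int
    auc: Optional[float] = None

    def as_dict(self, percent: bool = False) -> dict:
        out = dataclasses.asdict(self)
        if percent:
            for key, value in out.items():
                if key != "n" and value is not None:
                    out[key] = round(100.0 * value, 2)
        return out

    def as_row(self, method: str = "") -> dict:
        """Flat percentage row: Method, Accuracy, Precision, Specificity,
        Sensitivity, MCC, AUC, F1-Score, Err."""
        pct = self.as_dict(percent=True)
        return {
            "Method": method,
            "Accuracy": pct["accuracy"],
            "Precision": pct["precision"],
            "Specificity": pct["specificity"],
            "Sensitivity": pct["recall"],
            "MCC": pct["mcc"],
            "AUC": pct["auc"],
            "F1-Score": pct["f1"],
            "Err": pct["error_rate"],
        }


def confusion_counts(y_true: Sequence[int],
                     y_pred: Sequence[int]) -> ConfusionMatrix:
    """Count TP/TN/FP/FN for 0/1 label vectors (1 = pathogenic)."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    for vec, name in ((t, "y_true"), (p, "y_pred")):
        if not np.isin(vec, (0, 1)).all():
            raise ValueError(f"{name} contains non-binary values")
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", name)
        return 0.0
    return num / den


def matthews_cc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when a marginal is empty."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fn) * (tn + fp))
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / den


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between predicted and true labels."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
          + (cm.tn + cm.fn) * (cm.tn + cm.fp)) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def classification_metrics(cm: ConfusionMatrix,
                           auc: Optional[float] = None) -> MetricsReport:
    """All point metrics from one confusion matrix."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / n
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall")
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    f1 = _ratio(cm.tp, cm.tp + 0.5 * (cm.fn + cm.fp), "F1")
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        error_rate=1.0 - accuracy,
        mcc=matthews_cc(cm),
        f1=f1,
        kappa=cohen_kappa(cm),
        n=n,
        auc=auc,
    )


# Agreement bands for kappa.  The 0.60-0.79 interval, absent from the
# published banding, is filled with the conventional "Moderate" label so
# the scale is total; negative values fall in "None".
_KAPPA_BANDS = (
    (0.21, "None"),
    (0.40, "Minimal"),
    (0.60, "Weak"),
    (0.80, "Moderate"),
    (0.901, "Strong"),
    (float("inf"), "Almost perfect"),
)


def interpret_kappa(kappa: float) -> str:
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa out of [-1, 1]: {kappa}")
    for upper, label in _KAPPA_BANDS:
        if kappa < upper:
            return label
    raise AssertionError("unreachable")


@dataclasses.dataclass(frozen=True)
class RocCurve:
    """ROC points from a threshold sweep, and the trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> RocCurve:
    """Threshold sweep over the unique scores, ties stepped together."""
    t = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("length mismatch between labels and scores")
    if not np.isin(t, (0, 1)).all():
        raise ValueError("labels must be binary")
    n_pos = int(t.sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp_cum = np.cumsum(t_sorted)[distinct]
    fp_cum = np.cumsum(1 - t_sorted)[distinct]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


# Probability tiers for the pathogenicity score, as contiguous half-open
# intervals over [0, 1] so every score receives a tier.
TIER_LABELS = ("Benign", "Likely benign", "Uncertain",
               "Likely pathogenic", "Pathogenic")
_TIER_EDGES = (0.001, 0.05, 0.95, 0.99 + 1e-12)


def assign_tier(score: float) -> str:
    """Map a pathogenicity probability to its clinical-style tier.

    [0, 0.001) Benign; [0.001, 0.05) Likely benign; [0.05, 0.95)
    Uncertain; [0.95, 0.99] Likely pathogenic; (0.99, 1] Pathogenic.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score out of [0, 1]: {score}")
    for edge, label in zip(_TIER_EDGES, TIER_LABELS):
        if score < edge:
            return label
    return TIER_LABELS[-1]
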