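"""Detector evaluation metrics.

Per-class metrics follow the one-vs-rest convention: precision
TP/(TP+FP), recall (= sensitivity) TP/(TP+FN), specificity TN/(TN+FP),
F1 = 2PR/(P+R), and balanced accuracy = (recall + specificity)/2. Two
multi-class aggregates are distinguished because both appear in the
digital-health literature under the same name:

* Kelleher-style multi-class balanced accuracy — the mean per-class
  recall (macro-average recall);
* Urbanowicz–Moore multi-class balanced accuracy — the mean per-class
  balanced accuracy.

Ratios with a zero denominator are reported as NaN with a warning,
never silently as 0. ROC curves / AUC (one-vs-rest, trapezoidal) and
Bland–Altman limits of agreement (mean ± 1.96 sample SD of paired
differences) round out the evaluation toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classifier import CLASS_NAMES
from .decision import BreathPhase

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "RocCurve",
    "BlandAltmanStats",
    "confusion",
    "per_class_metrics",
    "f1_score",
    "balanced_accuracy",
    "multiclass_balanced_accuracy",
    "roc_auc",
    "bland_altman",
]

_PHASES = (BreathPhase.EXHALATION, BreathPhase.INHALATION, BreathPhase.NONBREATHING)


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts; rows true class, columns predicted, order (E, I, N)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 3) or np.any(counts < 0):
            raise ValueError("confusion matrix must be 3x3 with non-negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    specificity: float
    f1: float
    balanced_accuracy: float


@dataclass(frozen=True)
class MetricReport:
    per_class: dict[str, ClassMetrics]

    def macro(self, metric: str) -> float:
        return float(np.mean([getattr(m, metric) for m in self.per_class.values()]))

    @property
    def multiclass_ba_kelleher(self) -> float:
        return self.macro("recall")

    @property
    def multiclass_ba_urbanowicz(self) -> float:
        return self.macro("balanced_accuracy")

    def to_dict(self) -> dict:
        out = {
            name: vars(m) for name, m in self.per_class.items()
        }
        out["average"] = {
            k: self.macro(k)
            for k in ("precision", "recall", "specificity", "f1", "balanced_accuracy")
        }
        out["multiclass_balanced_accuracy"] = {
            "kelleher": self.multiclass_ba_kelleher,
            "urbanowicz": self.multiclass_ba_urbanowicz,
        }
        return out


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class BlandAltmanStats:
    differences: np.ndarray
    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float


def _phase_indices(phases) -> np.ndarray:
    return np.array([_PHASES.index(p) for p in phases])


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Cross-tabulate true vs predicted phases over the 3 detector classes."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    counts = _sk_confusion(
        _phase_indices(y_true), _phase_indices(y_pred), labels=[0, 1, 2]
    )
    return ConfusionMatrix(counts=counts)


def _ratio(num: float, den: float, name: str, cls: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined for class {cls!r} (zero denominator)",
                      stacklevel=3)
        return float("nan")
    return num / den


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def balanced_accuracy(recall: float, specificity: float) -> float:
    """Per-class balanced accuracy: mean of sensitivity and specificity."""
    return (recall + specificity) / 2.0


def per_class_metrics(cm: ConfusionMatrix) -> MetricReport:
    """One-vs-rest precision/recall/specificity/F1/balanced accuracy per class."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    report: dict[str, ClassMetrics] = {}
    for i, cls in enumerate(CLASS_NAMES):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = counts.sum() - tp - fn - fp
        precision = _ratio(tp, tp + fp, "precision", cls)
        recall = _ratio(tp, tp + fn, "recall", cls)
        specificity = _ratio(tn, tn + fp, "specificity", cls)
        report[cls] = ClassMetrics(
            precision=precision,
            recall=recall,
            specificity=specificity,
            f1=f1_score(precision, recall),
            balanced_accuracy=balanced_accuracy(recall, specificity),
        )
    return MetricReport(per_class=report)


def multiclass_balanced_accuracy(values, mode: str) -> float:
    """Aggregate per-class values into a multi-class balanced accuracy.

    ``values``: per-class recalls (mode "kelleher") or per-class balanced
    accuracies (mode "urbanowicz"); alternatively a MetricReport, from
    which the right column is taken.
    """
    if mode not in ("kelleher", "urbanowicz"):
        raise ValueError("mode must be 'kelleher' or 'urbanowicz'")
    if isinstance(values, MetricReport):
        column = "recall" if mode == "kelleher" else "balanced_accuracy"
        values = {c: getattr(m, column) for c, m in values.per_class.items()}
    if isinstance(values, dict):
        for cls, v in values.items():
            if not np.isfinite(v):
                raise ValueError(f"metric undefined for class {cls!r}")
        values = list(values.values())
    arr = np.asarray(list(values), dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("all per-class components must be defined")
    return float(arr.mean())


def roc_auc(scores, binary_labels) -> RocCurve:
    """One-vs-rest ROC with trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC undefined: both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores)
    # ensure explicit (0,0) and (1,1) endpoints
    if fpr[0] != 0.0 or tpr[0] != 0.0:
        fpr, tpr = np.insert(fpr, 0, 0.0), np.insert(tpr, 0, 0.0)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        fpr, tpr = np.append(fpr, 1.0), np.append(tpr, 1.0)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))


def bland_altman(x, y) -> BlandAltmanStats:
    """Limits of agreement for paired measurements: mean(d) ± 1.96·SD(d)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValueError("Bland–Altman requires at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanStats(
        differences=d,
        mean_difference=mean,
        sd_difference=sd,
        lower_limit=mean - 1.96 * sd,
        upper_limit=mean + 1.96 * sd,
    )
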