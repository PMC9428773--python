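"""Turn class probabilities into phase calls; threshold diagnostics.

The deployed detector does not simply take the argmax class: because the
feedback loop rewards exhalations, the exhalation probability is checked
against its threshold first, then inhalation, and only if both fail is
the frame called nonbreathing ("ordered" mode, default thresholds 0.3).
The plain argmax ("max" mode) is kept for comparison.

Threshold selection diagnostics: the Youden J statistic
(sensitivity + specificity − 1) maximized over observed scores, and
per-class true-positive-rate tables over a threshold grid under the
ordered policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .classifier import ClassProbabilities

DEFAULT_THRESHOLD = 0.3

__all__ = [
    "BreathPhase",
    "ThresholdPolicy",
    "ThresholdSearchResult",
    "apply_policy",
    "apply_policy_array",
    "youden_optimal_threshold",
    "tpr_by_threshold",
]


class BreathPhase(Enum):
    EXHALATION = "exhalation"
    INHALATION = "inhalation"
    NONBREATHING = "nonbreathing"
    UNCLEAR = "unclear"  # annotation-only; never a detector output


@dataclass(frozen=True)
class ThresholdPolicy:
    mode: str = "ordered"  # "ordered" or "max"
    tau_exhalation: float = DEFAULT_THRESHOLD
    tau_inhalation: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.mode not in ("ordered", "max"):
            raise ValueError("mode must be 'ordered' or 'max'")
        for tau in (self.tau_exhalation, self.tau_inhalation):
            if not 0.0 <= tau <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class ThresholdSearchResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_j: np.ndarray = field(init=False)
    optimal_threshold: float = field(init=False)
    optimal_j: float = field(init=False)

    def __post_init__(self) -> None:
        self.youden_j = self.sensitivity + self.specificity - 1.0
        best = int(np.argmax(self.youden_j))  # argmax returns first max: smallest tau
        self.optimal_threshold = float(self.thresholds[best])
        self.optimal_j = float(self.youden_j[best])


_PHASE_ORDER = (BreathPhase.EXHALATION, BreathPhase.INHALATION, BreathPhase.NONBREATHING)


def apply_policy(p: ClassProbabilities, policy: ThresholdPolicy) -> BreathPhase:
    """Classify one probability vector.

    Ordered mode: EXHALATION if p_ex >= tau_ex, else INHALATION if
    p_in >= tau_in, else NONBREATHING (thresholds inclusive). Max mode:
    the argmax class.
    """
    if policy.mode == "max":
        return _PHASE_ORDER[int(np.argmax(p.as_array()))]
    if p.p_exhalation >= policy.tau_exhalation:
        return BreathPhase.EXHALATION
    if p.p_inhalation >= policy.tau_inhalation:
        return BreathPhase.INHALATION
    return BreathPhase.NONBREATHING


def apply_policy_array(probs: np.ndarray, policy: ThresholdPolicy) -> list[BreathPhase]:
    """Vectorized :func:`apply_policy` over an (n, 3) probability matrix."""
    probs = np.asarray(probs, dtype=np.float64)
    if policy.mode == "max":
        idx = np.argmax(probs, axis=1)
    else:
        idx = np.where(
            probs[:, 0] >= policy.tau_exhalation,
            0,
            np.where(probs[:, 1] >= policy.tau_inhalation, 1, 2),
        )
    return [_PHASE_ORDER[i] for i in idx]


def youden_optimal_threshold(
    scores: np.ndarray, labels: np.ndarray
) -> ThresholdSearchResult:
    """Maximize J = sensitivity + specificity − 1 over candidate thresholds.

    The decision rule is score >= tau → positive. Candidates are the
    distinct observed scores plus 0 and 1 (J is piecewise constant in
    between). Ties go to the smallest maximizing threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Youden J undefined: both classes must be present")
    taus = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    pred = scores[None, :] >= taus[:, None]  # (n_taus, n_items)
    tp = (pred & labels[None, :]).sum(axis=1)
    tn = (~pred & ~labels[None, :]).sum(axis=1)
    return ThresholdSearchResult(
        thresholds=taus,
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
    )


def tpr_by_threshold(
    probs: np.ndarray, labels: list[BreathPhase], grid: np.ndarray
) -> pd.DataFrame:
    """Per-class recall under the ordered policy at each grid threshold.

    The same threshold is applied to exhalation first and then to
    inhalation, matching how a single shared threshold is tuned for the
    ordered policy. Returns a DataFrame indexed by threshold with one
    recall column per class.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    probs = np.asarray(probs, dtype=np.float64)
    true = np.array([_PHASE_ORDER.index(l) for l in labels])
    rows = []
    for tau in grid:
        policy = ThresholdPolicy(mode="ordered", tau_exhalation=tau, tau_inhalation=tau)
        pred = np.array([_PHASE_ORDER.index(p) for p in apply_policy_array(probs, policy)])
        row = {"threshold": float(tau)}
        for i, phase in enumerate(_PHASE_ORDER):
            mask = true == i
            row[f"tpr_{phase.value}"] = (
                float(np.mean(pred[mask] == i)) if mask.any() else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("threshold")
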