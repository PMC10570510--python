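"""Confusion-matrix metrics and Bayesian pre-/post-test probability.

Pneumonitis is the positive class everywhere in this package (coded 1;
pneumonia coded 0).  Sensitivity is the true-positive rate of pneumonitis
and specificity its true-negative rate.  The pre-test probability is the
prevalence of pneumonitis; the post-test probability given a positive
model call is the Bayesian positive predictive value

    P(D | +) = sens * prev / (sens * prev + (1 - spec) * (1 - prev)),

which equals the prevalence exactly when the positive likelihood ratio
sens / (1 - spec) is 1 (an uninformative test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "POSITIVE_CLASS",
    "ConfusionMatrix",
    "metrics",
    "pre_test",
    "post_test_positive",
    "to_percent",
]

#: single source of truth: pneumonitis is the positive class
POSITIVE_CLASS = 1


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")
        if self.n == 0:
            raise ValueError("confusion matrix is all zero")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); empty denominators give 0 with a warning."""
    accuracy = (cm.tp + cm.tn) / cm.n
    if cm.tp + cm.fn == 0:
        warnings.warn("no positive cases; sensitivity defined as 0", stacklevel=2)
        sensitivity = 0.0
    else:
        sensitivity = cm.tp / (cm.tp + cm.fn)
    if cm.tn + cm.fp == 0:
        warnings.warn("no negative cases; specificity defined as 0", stacklevel=2)
        specificity = 0.0
    else:
        specificity = cm.tn / (cm.tn + cm.fp)
    return accuracy, sensitivity, specificity


def pre_test(labels) -> float:
    """Prevalence of the positive class (pneumonitis) in a label vector."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    return float((labels == POSITIVE_CLASS).mean())


def post_test_positive(prevalence: float, sensitivity: float, specificity: float) -> float:
    """P(pneumonitis | positive model call) by Bayes' theorem."""
    for name, v in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("specificity", specificity),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    denom = sensitivity * prevalence + (1.0 - specificity) * (1.0 - prevalence)
    if denom == 0:
        raise ValueError(
            "the model never calls positive (sens * prev and (1 - spec) * (1 - prev) both 0)"
        )
    return sensitivity * prevalence / denom


def to_percent(p: float) -> int:
    """Round a probability to the nearest whole percent (half away from zero)."""
    return int(np.floor(100.0 * p + 0.5))
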