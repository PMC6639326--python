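"""Diagnostic-accuracy statistics.

Day-level detection is scored as a binary diagnostic test: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), each with an exact (Clopper-Pearson)
binomial 95% confidence interval.  Direction and frequency typing of the
true-positive events are scored as k-class confusion matrices with overall
accuracy = trace/total.  Sample-size planning uses the normal approximation
n = z^2 p(1-p) / d^2 for estimating a proportion p to margin d.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import beta


@dataclass
class ConfusionMatrix:
    """k x k count table; rows = ground truth, columns = prediction."""

    counts: np.ndarray
    class_labels: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k for k class labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_pairs(cls, truth: Sequence, predicted: Sequence, class_labels):
        labels = tuple(class_labels)
        index = {c: i for i, c in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(truth, predicted, strict=True):
            counts[index[t], index[p]] += 1
        return cls(counts, labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class DiagnosticAccuracy:
    """Sensitivity/specificity point estimates with exact binomial CIs."""

    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    ci_level: float = 0.95

    def summary(self) -> str:
        s = self
        return (
            f"sensitivity {100 * s.sensitivity:.1f}% "
            f"(95% CI: {100 * s.sens_ci[0]:.2f}% to {100 * s.sens_ci[1]:.2f}%), "
            f"specificity {100 * s.specificity:.1f}% "
            f"(95% CI: {100 * s.spec_ci[0]:.2f}% to {100 * s.spec_ci[1]:.2f}%)"
        )


@dataclass(frozen=True)
class PlanParams:
    """Sample-size plan: estimate a proportion ``target_mean`` to within
    ``margin`` at the given confidence."""

    target_mean: float = 0.98
    margin: float = 0.03
    confidence: float = 0.95

    def __post_init__(self):
        if not 0 < self.margin < self.target_mean < 1:
            raise ValueError("need 0 < margin < target_mean < 1")


def day_confusion(
    detections: dict[str, bool | int | list],
    ground_truth: dict[str, bool],
) -> ConfusionMatrix:
    """2x2 day-level confusion matrix.

    A day counts as predicted-present iff it has at least one accepted
    event (a non-empty list, or a truthy flag).  Labels are
    ('present', 'absent'), rows = ground truth.
    """
    if set(detections) != set(ground_truth):
        raise ValueError("detections and ground truth cover different days")
    truth, pred = [], []
    for name in ground_truth:
        truth.append("present" if ground_truth[name] else "absent")
        d = detections[name]
        positive = len(d) > 0 if isinstance(d, (list, tuple)) else bool(d)
        pred.append("present" if positive else "absent")
    return ConfusionMatrix.from_pairs(truth, pred, ("present", "absent"))


def clopper_pearson(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval via Beta quantiles.

    lower = Beta^{-1}(alpha/2; x, n-x+1) (0 when x = 0);
    upper = Beta^{-1}(1-alpha/2; x+1, n-x) (1 when x = n).
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"need 0 <= successes <= n, n >= 1; got {successes}/{n}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        beta.ppf(alpha / 2, successes, n - successes + 1)
    )
    upper = 1.0 if successes == n else float(
        beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return lower, upper


def sensitivity_specificity(
    cm: ConfusionMatrix, ci_level: float = 0.95
) -> DiagnosticAccuracy:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) from a 2x2 matrix
    whose first row/column is the positive class."""
    if cm.counts.shape != (2, 2):
        raise ValueError("a 2x2 confusion matrix is required")
    tp, fn = int(cm.counts[0, 0]), int(cm.counts[0, 1])
    fp, tn = int(cm.counts[1, 0]), int(cm.counts[1, 1])
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0:
        raise ValueError("sensitivity undefined: no truly positive days")
    if n_neg == 0:
        raise ValueError("specificity undefined: no truly negative days")
    return DiagnosticAccuracy(
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        sens_ci=clopper_pearson(tp, n_pos, ci_level),
        spec_ci=clopper_pearson(tn, n_neg, ci_level),
        n_pos=n_pos,
        n_neg=n_neg,
        ci_level=ci_level,
    )


def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval (alternative to the exact interval)."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"need 0 <= successes <= n, n >= 1; got {successes}/{n}")
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    p = successes / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def multiclass_accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy trace/total of a k x k confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def required_sample_size(plan: PlanParams) -> int:
    """Normal-approximation sample size ceil(z^2 p(1-p) / d^2)."""
    from scipy.stats import norm

    p, d = plan.target_mean, plan.margin
    if d >= min(p, 1 - p):
        warnings.warn(
            "margin is not small relative to p(1-p); the normal "
            "approximation may be poor",
            stacklevel=2,
        )
    z = norm.ppf(0.5 + plan.confidence / 2)
    return int(math.ceil(z**2 * p * (1 - p) / d**2))


def evaluate_trial(
    detections: dict[str, list],
    coding_sheet: dict[str, dict],
    classes: Sequence[float] = (0.8, 1.0, 1.2),
) -> dict:
    """Unblinded evaluation of a detection run against the coding sheet.

    Returns day-level detection results plus direction/frequency confusion
    matrices over the true-positive days (matching each truly positive,
    detected day's first accepted event to its ground-truth event).
    """
    from .event_typing import NystagmusEvent

    truth_flags = {
        name: entry["nystagmus_day"] for name, entry in coding_sheet.items()
    }
    cm = day_confusion(detections, truth_flags)
    acc = sensitivity_specificity(cm)

    dir_truth, dir_pred, freq_truth, freq_pred = [], [], [], []
    for name, entry in coding_sheet.items():
        if not entry["nystagmus_day"] or not detections.get(name):
            continue
        gt_events = [NystagmusEvent.from_dict(d) for d in entry["ground_truth"]]
        if not gt_events:
            continue
        gt = gt_events[0]
        det = detections[name][0]
        if det.direction is not None and gt.direction is not None:
            dir_truth.append(gt.direction)
            dir_pred.append(det.direction)
        if det.frequency_class is not None and gt.frequency_class is not None:
            freq_truth.append(gt.frequency_class)
            freq_pred.append(det.frequency_class)

    report = {
        "detection": {
            "confusion": cm,
            "accuracy": acc,
        }
    }
    if dir_truth:
        dcm = ConfusionMatrix.from_pairs(dir_truth, dir_pred, ("left", "right"))
        report["direction"] = {
            "confusion": dcm,
            "accuracy": multiclass_accuracy(dcm),
        }
    if freq_truth:
        fcm = ConfusionMatrix.from_pairs(freq_truth, freq_pred, tuple(sorted(classes)))
        report["frequency"] = {
            "confusion": fcm,
            "accuracy": multiclass_accuracy(fcm),
        }
    return report
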