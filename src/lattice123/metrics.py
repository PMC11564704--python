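"""Binary classification metrics for imbalanced two-class problems.

Reports a confusion matrix together with class-wise and overall (macro)
sensitivity, specificity, precision and F1, plus accuracy and the geometric
mean sqrt(sensitivity x specificity) — the latter is the imbalance-robust
headline metric.  Rates are expressed in percent; for a binary problem the
specificity of one class equals the sensitivity of the other, so the
geometric mean is also the square root of the product of the two class-wise
sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MetricsReport", "compute_metrics", "geometric_mean", "f1_score"]


def _round_half_up(x: float, digits: int = 2) -> float:
    return float(
        Decimal(repr(float(x))).quantize(Decimal(10) ** -digits, ROUND_HALF_UP)
    )


def geometric_mean(sensitivity_a: float, sensitivity_b: float) -> float:
    """sqrt of the product of the two class-wise sensitivities (percent in/out)."""
    if sensitivity_a < 0 or sensitivity_b < 0:
        raise ValueError("sensitivities must be non-negative")
    return float(np.sqrt(sensitivity_a * sensitivity_b))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same units in and out)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class MetricsReport:
    """Confusion matrix plus the class-wise/overall metric suite, in percent."""

    classes: tuple
    confusion: np.ndarray  # rows true, columns predicted
    accuracy: float
    sensitivity: dict = field(default_factory=dict)
    specificity: dict = field(default_factory=dict)
    precision: dict = field(default_factory=dict)
    f1: dict = field(default_factory=dict)
    macro_sensitivity: float = 0.0
    macro_specificity: float = 0.0
    macro_precision: float = 0.0
    macro_f1: float = 0.0
    geometric_mean: float = 0.0

    def to_frame(self, digits: int = 2) -> pd.DataFrame:
        """Display table, rates rounded half-up to ``digits`` decimals."""
        rows = []
        for metric, per_class, overall in (
            ("Sensitivity", self.sensitivity, self.macro_sensitivity),
            ("Specificity", self.specificity, self.macro_specificity),
            ("Precision", self.precision, self.macro_precision),
            ("F1-score", self.f1, self.macro_f1),
        ):
            for cls in self.classes:
                rows.append((metric, str(cls), _round_half_up(per_class[cls], digits)))
            rows.append((metric, "Overall", _round_half_up(overall, digits)))
        rows.append(("Accuracy", "Overall", _round_half_up(self.accuracy, digits)))
        rows.append(
            ("Geometric mean", "Overall", _round_half_up(self.geometric_mean, digits))
        )
        return pd.DataFrame(rows, columns=["Metric", "Class", "Result (%)"])

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": {str(k): v for k, v in self.sensitivity.items()},
            "specificity": {str(k): v for k, v in self.specificity.items()},
            "precision": {str(k): v for k, v in self.precision.items()},
            "f1": {str(k): v for k, v in self.f1.items()},
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "geometric_mean": self.geometric_mean,
        }


def compute_metrics(predicted: Sequence, truth: Sequence) -> MetricsReport:
    """Confusion matrix and the full metric suite (percent).

    Overall metrics other than accuracy are unweighted (macro) means of the
    class-wise values; the geometric mean multiplies the two class-wise
    sensitivities.
    """
    pred = np.asarray(predicted)
    y = np.asarray(truth)
    if pred.shape != y.shape:
        raise ValueError("predicted and truth must have equal length")
    classes = tuple(np.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes in truth, got {len(classes)}")
    unseen = set(np.unique(pred).tolist()) - set(classes)
    if unseen:
        raise ValueError(f"predictions contain labels not present in truth: {unseen}")

    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y, pred):
        confusion[index[t], index[p]] += 1

    total = confusion.sum()
    accuracy = 100.0 * confusion.trace() / total

    sens, spec, prec, f1 = {}, {}, {}, {}
    for c, i in index.items():
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens[c] = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        spec[c] = 100.0 * tn / (tn + fp) if tn + fp else 0.0
        prec[c] = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        f1[c] = f1_score(prec[c], sens[c])

    return MetricsReport(
        classes=classes,
        confusion=confusion,
        accuracy=accuracy,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
        macro_sensitivity=float(np.mean(list(sens.values()))),
        macro_specificity=float(np.mean(list(spec.values()))),
        macro_precision=float(np.mean(list(prec.values()))),
        macro_f1=float(np.mean(list(f1.values()))),
        geometric_mean=geometric_mean(*sens.values()),
    )
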