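"""Confusion-matrix construction and keratoconus-screening statistics.

Class order everywhere is (SPHERICAL, SYMMETRIC, ASYMMETRIC, IRREGULAR);
rows are the true class, columns the predicted class.  Percentages are
rounded half-up to two decimals, matching the printed style of clinical
reports.  The irregular (keratoconus) class is the screening-positive
class: sensitivity is the irregular-row diagonal over its row total, and
specificity the fraction of non-irregular images not called irregular.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .synth import CLASS_ORDER, ClassLabel

N_CLASSES = 4


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (Python's round() is half-even)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _label_index(lab) -> int:
    return CLASS_ORDER.index(ClassLabel(lab))


def confusion_matrix(pred: Sequence, truth: Sequence) -> np.ndarray:
    """4x4 counts, rows = truth, columns = prediction."""
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for p, t in zip(pred, truth):
        cm[_label_index(t), _label_index(p)] += 1
    return cm


def overall_accuracy(cm: np.ndarray) -> float:
    """Percent of correctly classified images, 100 * trace / total."""
    cm = np.asarray(cm)
    total = int(cm.sum())
    if total <= 0:
        raise ValueError("empty confusion matrix")
    return round2(100.0 * np.trace(cm) / total)


def per_class_rates(cm: np.ndarray) -> dict:
    """Per-class (correct %, error %) keyed by class label."""
    cm = np.asarray(cm)
    out = {}
    for i, lab in enumerate(CLASS_ORDER):
        row = cm[i].sum()
        if row <= 0:
            raise ValueError(f"empty row for {lab.value}")
        correct = 100.0 * cm[i, i] / row
        out[lab.value] = {"correct": round2(correct), "error": round2(100.0 - correct)}
    return out


@dataclass
class ScreeningMetrics:
    sensitivity: float
    specificity: float
    false_negative_rate: float
    false_positive_rate: float
    positive_class: ClassLabel = ClassLabel.IRREGULAR


def screening_metrics(
    cm: np.ndarray, positive: ClassLabel = ClassLabel.IRREGULAR
) -> ScreeningMetrics:
    """Sensitivity/specificity with ``positive`` as the screening class."""
    cm = np.asarray(cm)
    p = _label_index(positive)
    pos_total = int(cm[p].sum())
    neg_total = int(cm.sum() - pos_total)
    if pos_total <= 0 or neg_total <= 0:
        raise ValueError("need both positive and negative samples")
    sens = 100.0 * cm[p, p] / pos_total
    neg_rows = [i for i in range(N_CLASSES) if i != p]
    fp = int(cm[neg_rows, p].sum())
    spec = 100.0 * (neg_total - fp) / neg_total
    return ScreeningMetrics(
        sensitivity=round2(sens),
        specificity=round2(spec),
        false_negative_rate=round2(100.0 - sens),
        false_positive_rate=round2(100.0 - spec),
        positive_class=ClassLabel(positive),
    )


def published_test_matrix() -> np.ndarray:
    """The published 212-image test confusion matrix, reconstructed from the
    per-class error narratives and row totals of the original clinical
    evaluation: spherical 34/35 (1 called irregular); symmetric 58/62
    (3 asymmetric, 1 irregular); asymmetric 52/55 (3 symmetric); irregular
    57/60 (1 symmetric, 2 asymmetric)."""
    return np.array(
        [
            [34, 0, 0, 1],
            [0, 58, 3, 1],
            [0, 3, 52, 0],
            [0, 1, 2, 57],
        ],
        dtype=int,
    )


def report(cm: np.ndarray, positive: ClassLabel = ClassLabel.IRREGULAR) -> dict:
    """Full evaluation report mirroring the published table layout."""
    cm = np.asarray(cm)
    scr = screening_metrics(cm, positive)
    acc = overall_accuracy(cm)
    return {
        "class_order": [c.value for c in CLASS_ORDER],
        "confusion_matrix": cm.tolist(),
        "n": int(cm.sum()),
        "overall_accuracy": acc,
        "overall_error": round2(100.0 - acc),
        "per_class": per_class_rates(cm),
        "screening": {
            "positive_class": scr.positive_class.value,
            "sensitivity": scr.sensitivity,
            "specificity": scr.specificity,
            "false_negative_rate": scr.false_negative_rate,
            "false_positive_rate": scr.false_positive_rate,
        },
    }
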