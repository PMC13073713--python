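"""Three-class evaluation: confusion counts, accuracy, per-class
precision/recall/F1, macro and class-weighted F1, and one-vs-rest AUC.

The per-class AUC uses the rank-sum (Mann-Whitney) formulation with
midrank tie handling, which equals trapezoidal integration of the
one-vs-rest ROC curve.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

CLASS_NAMES = ("low", "medium", "high")
N_CLASSES = 3


def round2(x: float) -> float:
    """Report-style rounding: two decimals, round-half-even."""
    return round(float(x), 2)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean; 0 when both terms are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_average(values) -> float:
    """Unweighted mean of per-class values."""
    values = np.asarray(values, dtype=float)
    return float(values.mean())


def weighted_average(values, class_counts) -> float:
    """Per-class values averaged with weights n_c / N."""
    values = np.asarray(values, dtype=float)
    counts = np.asarray(class_counts, dtype=float)
    return float((values * counts).sum() / counts.sum())


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if y.size == 0:
        raise ValueError("empty label vector")
    if not np.isin(y, [0, 1, 2]).all():
        bad = sorted(set(y.tolist()) - {0, 1, 2})
        raise ValueError(f"labels outside {{0, 1, 2}}: {bad}")
    return y


def confusion_matrix3(y_true, y_pred) -> np.ndarray:
    """3x3 counts, rows = true class, columns = predicted class."""
    y_true = _check_labels(y_true)
    y_pred = _check_labels(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0): reported as 0", what)
        return 0.0
    return num / den


@dataclass
class MetricsReport:
    """All scalar metrics for one model on one evaluation set."""

    accuracy: float
    precision: tuple[float, float, float]
    recall: tuple[float, float, float]
    f1: tuple[float, float, float]
    macro_f1: float
    weighted_f1: float
    class_counts: tuple[int, int, int]
    auc: tuple[float, float, float] | None = None
    macro_auc: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def classification_report(y_true, y_pred) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1, macro-F1 and weighted-F1
    (weights are class shares of ``y_true``); 0/0 rates report 0."""
    cm = confusion_matrix3(y_true, y_pred)
    n = int(cm.sum())
    tp = np.diag(cm)
    precision = []
    recall = []
    f1 = []
    for c in range(N_CLASSES):
        p = _safe_div(tp[c], cm[:, c].sum(), f"precision[{CLASS_NAMES[c]}]")
        r = _safe_div(tp[c], cm[c, :].sum(), f"recall[{CLASS_NAMES[c]}]")
        precision.append(float(p))
        recall.append(float(r))
        f1.append(f1_from_precision_recall(p, r))
    counts = tuple(int(x) for x in cm.sum(axis=1))
    return MetricsReport(
        accuracy=float(tp.sum() / n),
        precision=tuple(precision),
        recall=tuple(recall),
        f1=tuple(f1),
        macro_f1=macro_average(f1),
        weighted_f1=weighted_average(f1, counts),
        class_counts=counts,
    )


def _auc_binary(positive: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank ties == trapezoidal OvR ROC area."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    ranks = rankdata(scores)  # midranks
    rank_sum = ranks[positive].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_auc_ovr(y_true, scores) -> tuple[float, float, float, float]:
    """Per-class one-vs-rest AUC (columns of ``scores`` ordered low,
    medium, high) plus their unweighted mean."""
    y_true = _check_labels(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (y_true.size, N_CLASSES):
        raise ValueError("scores must be N x 3")
    aucs = []
    for c in range(N_CLASSES):
        positive = y_true == c
        if positive.all() or not positive.any():
            raise ValueError(
                f"class {CLASS_NAMES[c]} lacks positives or negatives"
            )
        aucs.append(_auc_binary(positive, scores[:, c]))
    return (*aucs, macro_average(aucs))


def attach_auc(report: MetricsReport, y_true, scores) -> MetricsReport:
    a_low, a_med, a_high, macro = roc_auc_ovr(y_true, scores)
    report.auc = (a_low, a_med, a_high)
    report.macro_auc = macro
    return report
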