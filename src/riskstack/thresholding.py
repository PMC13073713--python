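"""Threshold sweep over the high-risk cutoff, minimal-best-F1 selection,
and one-vs-rest precision-recall curves."""

from __future__ import annotations

import numpy as np
import pandas as pd

from riskstack.ensemble import decide_labels
from riskstack.metrics import classification_report

RISK_HIGH = 2
DEFAULT_GRID = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))


def threshold_metric_curve(
    y_true, P_final: np.ndarray, grid=DEFAULT_GRID
) -> pd.DataFrame:
    """Per-threshold, per-class precision/recall/F1 table.

    One row per (tau, class); labels at each tau come from the high-risk
    threshold decision rule.
    """
    grid = [float(t) for t in grid]
    if not grid:
        raise ValueError("empty threshold grid")
    if sorted(grid) != grid or len(set(grid)) != len(grid):
        raise ValueError("grid must be strictly increasing")
    P_final = np.asarray(P_final, dtype=float)
    rows = []
    prev_high = None
    for tau in grid:
        labels = decide_labels(P_final, tau)
        n_high = int((labels == RISK_HIGH).sum())
        if prev_high is not None and n_high > prev_high:
            raise AssertionError("high-prediction count increased with tau")
        prev_high = n_high
        rep = classification_report(y_true, labels)
        for c, name in enumerate(("low", "medium", "high")):
            rows.append(
                {
                    "tau": tau,
                    "class": name,
                    "precision": rep.precision[c],
                    "recall": rep.recall[c],
                    "f1": rep.f1[c],
                }
            )
    return pd.DataFrame(rows)


def select_optimal_threshold(
    curve: pd.DataFrame, target_class: str = "high"
) -> float:
    """Smallest grid threshold whose target-class F1 attains the maximum."""
    sub = curve[curve["class"] == target_class]
    if sub.empty:
        raise ValueError(f"no rows for class {target_class!r}")
    sub = sub.sort_values("tau")
    best = sub["f1"].max()
    return float(sub.loc[sub["f1"] >= best, "tau"].iloc[0])


def precision_recall_curve_ovr(
    y_true, scores: np.ndarray, target_class: int
) -> pd.DataFrame:
    """One-vs-rest PR points at every distinct score cutoff.

    Cutoffs are the distinct scores in increasing order; at cutoff t a
    sample is predicted positive iff its score >= t, so the lowest cutoff
    attains recall 1.  Returns columns (cutoff, recall, precision).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    positive = y_true == target_class
    if not positive.any() or positive.all():
        raise ValueError(
            f"class {target_class} needs at least one positive and one negative"
        )
    rows = []
    for cutoff in np.unique(scores):
        predicted = scores >= cutoff
        tp = int((predicted & positive).sum())
        precision = tp / int(predicted.sum())
        recall = tp / int(positive.sum())
        rows.append({"cutoff": float(cutoff), "recall": recall,
                     "precision": precision})
    return pd.DataFrame(rows)
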