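"""Evaluation metrics for the imbalanced anticancer classification task.

With only ~10% positives, accuracy is uninformative; the metrics of record
are balanced accuracy (mean of per-class recalls), F1 of the positive
(anticancer) class, and AUPR computed as average precision (the step-wise sum
Δrecall x precision over the score-sorted sweep, ties handled as one
threshold step, no interpolation).  All values are reported as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve

__all__ = ["MetricsReport", "confusion_counts", "summary_metrics", "mean_pr_curve",
           "aggregate_reports"]


@dataclass
class MetricsReport:
    """Percent-scale summary of one evaluation split."""

    balanced_accuracy: float
    f1_positive: float
    aupr: float
    precision_pos: float
    recall_pos: float
    precision_neg: float
    recall_neg: float
    counts: tuple[int, int, int, int]  # (TP, FP, TN, FN)
    pr_curve: list[tuple[float, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "f1_positive": self.f1_positive,
            "aupr": self.aupr,
            "precision_pos": self.precision_pos,
            "recall_pos": self.recall_pos,
            "precision_neg": self.precision_neg,
            "recall_neg": self.recall_neg,
            "counts": list(self.counts),
        }


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return a.astype(np.int64)


def confusion_counts(y_true, y_pred) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with positive = anticancer."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, fp, tn, fn


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def summary_metrics(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Score a split from anticancer probabilities.

    Class predictions are argmax, i.e. score >= ``threshold`` (default 0.5).
    AUPR is average precision; it requires both classes present.
    """
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=np.float64)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0,1]")
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUPR undefined for single-class y_true")
    y_pred = (scores >= threshold).astype(np.int64)
    tp, fp, tn, fn = confusion_counts(y_true, y_pred)
    recall_pos = _safe_div(tp, tp + fn)
    recall_neg = _safe_div(tn, tn + fp)
    precision_pos = _safe_div(tp, tp + fp)
    precision_neg = _safe_div(tn, tn + fn)
    f1 = _safe_div(2 * precision_pos * recall_pos, precision_pos + recall_pos)
    aupr = float(average_precision_score(y_true, scores))
    prec, rec, _ = precision_recall_curve(y_true, scores)
    # sklearn returns the sweep in decreasing-recall order; store ascending
    curve = sorted(zip(rec.tolist(), prec.tolist()))
    return MetricsReport(
        balanced_accuracy=100.0 * (recall_pos + recall_neg) / 2.0,
        f1_positive=100.0 * f1,
        aupr=100.0 * aupr,
        precision_pos=100.0 * precision_pos,
        recall_pos=100.0 * recall_pos,
        precision_neg=100.0 * precision_neg,
        recall_neg=100.0 * recall_neg,
        counts=(tp, fp, tn, fn),
        pr_curve=curve,
    )


def _step_lookup(curve: list[tuple[float, float]], r: float) -> float:
    """Right-continuous precision lookup: precision of the first point with recall >= r."""
    for rec, prec in curve:  # curve sorted by ascending recall
        if rec >= r - 1e-12:
            return prec
    return curve[-1][1]


def mean_pr_curve(per_fold_curves: list[list[tuple[float, float]]],
                  grid_step: float = 0.01) -> list[tuple[float, float]]:
    """Vertically average PR curves on a fixed recall grid (0, step, ..., 1)."""
    if not per_fold_curves:
        raise ValueError("need at least one curve")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    out = []
    for r in grid:
        vals = [_step_lookup(sorted(c), float(r)) for c in per_fold_curves]
        out.append((float(r), float(np.mean(vals))))
    return out


def aggregate_reports(reports: list[MetricsReport]):
    """Mean ± sample std across folds, as a pandas DataFrame in percent."""
    import pandas as pd

    fields = ["balanced_accuracy", "f1_positive", "aupr",
              "precision_pos", "recall_pos", "precision_neg", "recall_neg"]
    rows = {}
    for f in fields:
        vals = np.array([getattr(r, f) for r in reports], dtype=float)
        rows[f] = {"mean": vals.mean(), "std": vals.std(ddof=1) if len(vals) > 1 else 0.0}
    return pd.DataFrame(rows).T
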