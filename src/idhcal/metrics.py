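"""Subject-level evaluation: classification metrics, pooling, Brier score.

Conventions, fixed package-wide: IDH-wildtype is the positive class (y = 1),
so recall coincides with the wildtype-class accuracy by definition.
Percent-scale values appear only at the reporting boundary; everything is
computed at full precision and rounded (one decimal) only when printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCells",
    "ClassificationMetrics",
    "confusion_cells",
    "classification_metrics",
    "pooled_weighted",
    "f1_from_precision_recall",
    "pool_confusions",
    "brier",
    "reliability_bins",
]


@dataclass(frozen=True)
class ConfusionCells:
    """Binary confusion-matrix cells with wildtype as the positive class."""

    tp: int  # wildtype called wildtype
    fp: int  # mutant called wildtype
    tn: int  # mutant called mutant
    fn: int  # wildtype called mutant

    @property
    def n_wildtype(self) -> int:
        return self.tp + self.fn

    @property
    def n_mutant(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ClassificationMetrics:
    """Percent-scale subject-level metrics (AUC on [0, 1], as reported)."""

    n: int
    n_mutant: int
    n_wildtype: int
    accuracy: float
    accuracy_mutant_class: float | None
    accuracy_wildtype_class: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    auc: float | None
    undefined: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n", "n_mutant", "n_wildtype", "accuracy", "accuracy_mutant_class",
            "accuracy_wildtype_class", "precision", "recall", "f1", "auc")}
        if self.undefined:
            d["undefined"] = dict(self.undefined)
        return d


def confusion_cells(true_labels, predicted_labels) -> ConfusionCells:
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    return ConfusionCells(
        tp=int(((t == "wildtype") & (p == "wildtype")).sum()),
        fp=int(((t == "mutant") & (p == "wildtype")).sum()),
        tn=int(((t == "mutant") & (p == "mutant")).sum()),
        fn=int(((t == "wildtype") & (p == "mutant")).sum()),
    )


def _metrics_from_cells(cells: ConfusionCells, auc: float | None,
                        undefined: dict) -> ClassificationMetrics:
    n = cells.total
    acc = 100.0 * (cells.tp + cells.tn) / n
    acc_mut = 100.0 * cells.tn / cells.n_mutant if cells.n_mutant else None
    acc_wt = 100.0 * cells.tp / cells.n_wildtype if cells.n_wildtype else None
    called_pos = cells.tp + cells.fp
    precision = 100.0 * cells.tp / called_pos if called_pos else None
    recall = acc_wt
    denom = 2 * cells.tp + cells.fp + cells.fn
    f1 = 100.0 * 2 * cells.tp / denom if denom else None
    if cells.n_mutant == 0 or cells.n_wildtype == 0:
        undefined.setdefault("precision", "single-class cohort")
        undefined.setdefault("auc", "single-class cohort")
        auc = None
    if precision is None:
        undefined.setdefault("precision", "no wildtype calls")
    return ClassificationMetrics(
        n=n, n_mutant=cells.n_mutant, n_wildtype=cells.n_wildtype,
        accuracy=acc, accuracy_mutant_class=acc_mut, accuracy_wildtype_class=acc_wt,
        precision=precision, recall=recall, f1=f1, auc=auc, undefined=undefined,
    )


def classification_metrics(frame: pd.DataFrame, score_col: str = "x") -> ClassificationMetrics:
    """Score subject-level calls against truth.

    ``frame`` needs true_label, predicted_label and a score column (the
    wildtype fraction by default) for the rank-based AUC (midrank ties,
    equivalent to the trapezoidal ROC area). Single-class cohorts report
    AUC/precision as undefined with a reason instead of a number.
    """
    from sklearn.metrics import roc_auc_score

    required = {"true_label", "predicted_label", score_col}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    cells = confusion_cells(frame["true_label"], frame["predicted_label"])
    undefined: dict = {}
    auc = None
    if cells.n_mutant and cells.n_wildtype:
        y = (frame["true_label"] == "wildtype").to_numpy(dtype=int)
        auc = float(roc_auc_score(y, frame[score_col].to_numpy(dtype=float)))
    else:
        undefined["auc"] = "single-class cohort"
    return _metrics_from_cells(cells, auc, undefined)


def pooled_weighted(values, weights) -> float:
    """Count-weighted arithmetic pooling sum(w*v)/sum(w) at full precision.

    The reporting layer rounds to one decimal; nothing is rounded here.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(values * weights) / np.sum(weights))


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of (pooled) precision and recall, same scale in/out."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def pool_confusions(cells_list) -> ConfusionCells:
    """Exact pooling across cohorts by summing confusion-matrix cells."""
    return ConfusionCells(
        tp=sum(c.tp for c in cells_list),
        fp=sum(c.fp for c in cells_list),
        tn=sum(c.tn for c in cells_list),
        fn=sum(c.fn for c in cells_list),
    )


def metrics_from_confusion(cells: ConfusionCells) -> ClassificationMetrics:
    """Percent-scale metrics from confusion cells alone (no AUC)."""
    return _metrics_from_cells(cells, auc=None, undefined={"auc": "needs scores"})


def brier(scores, y) -> float:
    """Mean squared error between probabilistic scores and binary outcomes.

    ``y`` = 1 for wildtype. Applied identically to raw wildtype fractions
    (treated as probabilities) and to calibrated confidence scores.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    if scores.shape != y.shape or scores.size == 0:
        raise ValueError("scores and outcomes must be equal-length and non-empty")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    return float(np.mean((scores - y) ** 2))


def reliability_bins(scores, y, n_bins: int = 10) -> pd.DataFrame:
    """Reliability-diagram data: equal-width bins of the score axis.

    Returns bin edges, per-bin count, mean score and observed wildtype
    rate (NaN for empty bins).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        rows.append({
            "bin_low": edges[b],
            "bin_high": edges[b + 1],
            "count": int(mask.sum()),
            "mean_score": float(scores[mask].mean()) if mask.any() else np.nan,
            "outcome_rate": float(y[mask].mean()) if mask.any() else np.nan,
        })
    return pd.DataFrame(rows)
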