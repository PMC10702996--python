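"""Multi-class diagnostic metrics: one-vs-rest confusion counts, the
accuracy / sensitivity / specificity / precision / F-measure suite, macro
averaging, and ROC/AUC by threshold sweep.

Sensitivity follows the standard Recall definition TP/(TP+FN).  A printed
variant TP/(TP+FP) circulates in some write-ups (a transcription slip that
collapses sensitivity onto precision); it is selectable via
``sensitivity_formula="printed"`` but not the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "metric_suite",
    "macro_average",
    "roc_auc",
    "multiclass_roc_auc",
    "classification_report",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f_measure")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred, n_classes: int) -> list[ConfusionCounts]:
    """Per-class one-vs-rest confusion counts."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    out = []
    for c in range(n_classes):
        t = y_true == c
        p = y_pred == c
        out.append(ConfusionCounts(
            tp=int(np.sum(t & p)),
            fp=int(np.sum(~t & p)),
            tn=int(np.sum(~t & ~p)),
            fn=int(np.sum(t & ~p)),
        ))
    return out


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metric_suite(counts: ConfusionCounts,
                 sensitivity_formula: str = "recall") -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision and F-measure.

    Division by zero yields the sentinel 0.0 and a RuntimeWarning.
    """
    c = counts
    zero_div = False
    accuracy, z = _safe_div(c.tp + c.tn, c.total); zero_div |= z
    if sensitivity_formula == "recall":
        sensitivity, z = _safe_div(c.tp, c.tp + c.fn)
    elif sensitivity_formula == "printed":
        sensitivity, z = _safe_div(c.tp, c.tp + c.fp)
    else:
        raise ValueError(f"unknown sensitivity_formula {sensitivity_formula!r}")
    zero_div |= z
    specificity, z = _safe_div(c.tn, c.tn + c.fp); zero_div |= z
    precision, z = _safe_div(c.tp, c.tp + c.fp); zero_div |= z
    recall, _ = _safe_div(c.tp, c.tp + c.fn)
    f_measure, z = _safe_div(2.0 * precision * recall, precision + recall)
    zero_div |= z
    if zero_div:
        warnings.warn("zero denominator in metric computation; sentinel 0 used",
                      RuntimeWarning, stacklevel=2)
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "f_measure": f_measure,
    }


def macro_average(per_class: list[dict[str, float]],
                  supports: list[int] | None = None) -> dict[str, float]:
    """Unweighted (macro) or support-weighted mean of per-class metrics."""
    if not per_class:
        raise ValueError("per_class metrics must be non-empty")
    keys = per_class[0].keys()
    if supports is None:
        w = np.ones(len(per_class))
    else:
        w = np.asarray(supports, dtype=np.float64)
        if len(w) != len(per_class):
            raise ValueError("supports length mismatch")
    w = w / w.sum()
    return {k: float(sum(wi * m[k] for wi, m in zip(w, per_class))) for k in keys}


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """Binary ROC by threshold sweep over unique scores; AUC by trapezoid.

    Tied scores cross their threshold simultaneously.  Returns the array of
    (FPR, TPR) points (including (0,0) and (1,1)) and the AUC.
    """
    y_true = np.asarray(y_true).astype(np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape:
        raise ValueError("length mismatch between labels and scores")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    s = scores[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # Keep only the last point of each tied-score group.
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def multiclass_roc_auc(y_true, score_matrix) -> tuple[dict[int, np.ndarray], float]:
    """One-vs-rest ROC curves per class plus the macro-averaged AUC."""
    score_matrix = np.asarray(score_matrix, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.int64)
    curves: dict[int, np.ndarray] = {}
    aucs = []
    for c in range(score_matrix.shape[1]):
        pts, auc = roc_auc((y_true == c).astype(int), score_matrix[:, c])
        curves[c] = pts
        aucs.append(auc)
    return curves, float(np.mean(aucs))


def classification_report(y_true, y_pred, n_classes: int,
                          score_matrix=None) -> dict:
    """Per-class metric suites, macro/weighted averages, and optional AUC."""
    counts = confusion(y_true, y_pred, n_classes)
    per_class = [metric_suite(c) for c in counts]
    supports = [c.tp + c.fn for c in counts]
    report = {
        "per_class": per_class,
        "macro": macro_average(per_class),
        "weighted": macro_average(per_class, supports),
        "support": supports,
        "counts": [vars(c) for c in counts],
    }
    if score_matrix is not None:
        _, macro_auc = multiclass_roc_auc(y_true, score_matrix)
        report["macro_auc"] = macro_auc
    return report
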