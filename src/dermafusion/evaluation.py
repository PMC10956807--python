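"""Multiclass confusion-matrix metrics and reporting.

Every classifier run is summarized by a K x K confusion matrix
(rows = actual class, columns = predicted class) from which
one-vs-rest TP/FP/FN/TN counts, accuracy, precision, sensitivity
(recall), specificity and a trapezoidal one-vs-rest ROC AUC are
derived per class, plus macro (unweighted) means and the overall
pooled accuracy.

Two per-class "accuracy" flavors are reported because published
per-class tables are ambiguous between them: ``accuracy`` is the
one-vs-rest (TP+TN)/n, and ``within_class_accuracy`` the diagonal
fraction of the class row (identical to sensitivity).  Alongside the
standard AUC the report carries ``rate_ratio``, the TPR/FPR ratio at
the best Youden operating point, for completeness — it is a ratio of
rates, not an area, and is not a substitute for the AUC column.

Zero-denominator metrics are marked undefined with NaN rather than
raised.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ClassMetrics",
    "MetricsReport",
    "confusion_matrix",
    "class_metrics",
    "roc_auc",
    "aggregate_report",
]


def confusion_matrix(
    y_true: Sequence[int], y_pred: Sequence[int], K: int
) -> np.ndarray:
    """K x K counts with entry (i, j) = #{actual i, predicted j}."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if yt.size and (yt.min() < 0 or yt.max() >= K or yp.min() < 0 or yp.max() >= K):
        raise ValueError(f"labels must lie in 0..{K - 1}")
    cm = np.zeros((K, K), dtype=np.int64)
    np.add.at(cm, (yt, yp), 1)
    return cm


@dataclass
class ClassMetrics:
    """One-vs-rest counts and percentage metrics for a single class."""

    class_index: int
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float  # (TP+TN)/n * 100
    within_class_accuracy: float  # TP / row total * 100 (= sensitivity)
    precision: float
    sensitivity: float
    specificity: float
    auc: float = float("nan")
    rate_ratio: float = float("nan")


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def class_metrics(cm: np.ndarray, class_index: int) -> ClassMetrics:
    """One-vs-rest metrics for one class; NaN marks undefined ratios."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if not 0 <= class_index < cm.shape[0]:
        raise ValueError("class_index out of range")
    k = class_index
    n = int(cm.sum())
    tp = int(cm[k, k])
    fp = int(cm[:, k].sum() - tp)
    fn = int(cm[k, :].sum() - tp)
    tn = n - tp - fp - fn
    return ClassMetrics(
        class_index=k,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=_pct(tp + tn, n),
        within_class_accuracy=_pct(tp, tp + fn),
        precision=_pct(tp, tp + fp),
        sensitivity=_pct(tp, tp + fn),
        specificity=_pct(tn, tn + fp),
    )


def _roc_points(
    scores: np.ndarray, positive: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) swept over score thresholds, ties grouped."""
    order = np.argsort(-scores, kind="stable")
    pos = positive[order].astype(float)
    neg = 1.0 - pos
    tp = np.cumsum(pos)
    fp = np.cumsum(neg)
    # keep only the last point of each tied-score group
    s = scores[order]
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    P, N = positive.sum(), (~positive.astype(bool)).sum()
    tpr = np.r_[0.0, tp / P] if P > 0 else np.r_[0.0, np.full(tp.size, np.nan)]
    fpr = np.r_[0.0, fp / N] if N > 0 else np.r_[0.0, np.full(fp.size, np.nan)]
    return fpr, tpr


def roc_auc(
    scores: np.ndarray,
    y_true: Sequence[int],
    class_index: int,
    return_ratio: bool = False,
):
    """One-vs-rest trapezoidal area under the ROC curve.

    ``scores`` is the (n, K) score matrix; column ``class_index`` is
    the positive-class score.  With ``return_ratio=True`` also returns
    the raw TPR/FPR ratio at the operating point maximizing Youden's
    J (infinity when that FPR is zero) — a legacy summary, not an
    area.  Returns NaN when the class is absent from ``y_true``.
    """
    S = np.asarray(scores, dtype=float)
    yt = np.asarray(y_true, dtype=int)
    if S.ndim != 2 or S.shape[0] != yt.shape[0]:
        raise ValueError("scores must be (n, K) aligned with y_true")
    if not np.all(np.isfinite(S)):
        raise ValueError("scores contain non-finite values")
    positive = (yt == class_index).astype(int)
    if positive.sum() == 0 or positive.sum() == len(yt):
        out = float("nan")
        return (out, float("nan")) if return_ratio else out
    fpr, tpr = _roc_points(S[:, class_index], positive)
    auc = float(np.trapezoid(tpr, fpr))
    if not return_ratio:
        return auc
    j = tpr - fpr
    best = int(np.argmax(j))
    ratio = float(tpr[best] / fpr[best]) if fpr[best] > 0 else float("inf")
    return auc, ratio


@dataclass
class MetricsReport:
    """Per-class metrics plus aggregates.

    ``aggregate`` holds macro (unweighted across classes) means of the
    per-class columns and ``overall_accuracy`` = trace(cm)/n * 100,
    which are different summaries and labeled as such.
    """

    per_class: list[ClassMetrics]
    aggregate: dict[str, float]
    confusion: list[list[int]]
    n: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n": self.n,
            "confusion": self.confusion,
            "per_class": [asdict(m) for m in self.per_class],
            "aggregate": self.aggregate,
        }
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame([asdict(m) for m in self.per_class]).to_csv(path, index=False)


def aggregate_report(
    cm: np.ndarray,
    scores: np.ndarray | None = None,
    y_true: Sequence[int] | None = None,
) -> MetricsReport:
    """Full per-class + aggregate report from a confusion matrix.

    AUC columns are filled only when ``scores`` and ``y_true`` are
    supplied.  Macro means skip NaN (undefined) entries.
    """
    cm = np.asarray(cm, dtype=np.int64)
    K = cm.shape[0]
    per_class = [class_metrics(cm, k) for k in range(K)]
    if scores is not None:
        if y_true is None:
            raise ValueError("y_true is required when scores are given")
        for k in range(K):
            auc, ratio = roc_auc(scores, y_true, k, return_ratio=True)
            per_class[k].auc = auc * 100.0  # report columns are percentages
            per_class[k].rate_ratio = ratio
    n = int(cm.sum())

    def macro(attr: str) -> float:
        vals = np.array([getattr(m, attr) for m in per_class], dtype=float)
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    aggregate = {
        "overall_accuracy": _pct(np.trace(cm), n),
        "macro_accuracy": macro("accuracy"),
        "macro_precision": macro("precision"),
        "macro_sensitivity": macro("sensitivity"),
        "macro_specificity": macro("specificity"),
        "macro_auc": macro("auc"),
    }
    return MetricsReport(
        per_class=per_class,
        aggregate=aggregate,
        confusion=cm.tolist(),
        n=n,
    )
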