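"""Diagnostic-test evaluation: confusion metrics, ROC curves and AUC.

Two independent AUC routes are provided and must agree on every input:

* :func:`auc_rank` — the probability that a random positive outranks a
  random negative (Mann–Whitney form, ties counted 1/2);
* :func:`auc_trapezoid` — trapezoidal integration of the empirical ROC
  curve built by :func:`roc_points` (tied scores grouped into one step, so
  ties contribute diagonal segments, the same 1/2 convention).

Undefined ratios (zero denominator) are reported as ``None``, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

POSITIVE_LABELS = frozenset({"cancer", "cancer_present", "case", "1", 1, True})
NEGATIVE_LABELS = frozenset(
    {"normal", "cancer_absent", "control", "noncancer", "0", 0, False}
)


def as_binary_truth(truth) -> pd.Series:
    """Coerce a truth vector (ints, bools or label strings) to booleans."""
    s = pd.Series(truth)
    out = pd.Series(index=s.index, dtype=bool)
    for idx, v in s.items():
        if v in POSITIVE_LABELS:
            out[idx] = True
        elif v in NEGATIVE_LABELS:
            out[idx] = False
        else:
            raise ValueError(f"unrecognised truth label {v!r} for sample {idx!r}")
    return out


@dataclass
class PerformanceReport:
    """Confusion counts, derived diagnostic metrics, ROC points and AUC."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    npv: float | None
    ppv: float | None
    roc_points: np.ndarray | None = None  # (n, 2) array of (FPR, TPR)
    auc: float | None = None
    n_unclassifiable: int = 0

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "TP": self.tp,
                "FP": self.fp,
                "TN": self.tn,
                "FN": self.fn,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "NPV": self.npv,
                "PPV": self.ppv,
                "AUC": self.auc,
                "n_unclassifiable": self.n_unclassifiable,
            }
        )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(calls, truth, n_unclassifiable: int = 0) -> PerformanceReport:
    """Confusion counts and derived metrics from binary calls vs truth."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth differ in length")
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    tn = int(np.sum(~calls & ~truth))
    fn = int(np.sum(~calls & truth))
    return PerformanceReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        npv=_ratio(tn, tn + fn),
        ppv=_ratio(tp, tp + fp),
        n_unclassifiable=n_unclassifiable,
    )


def auc_rank(scores, truth) -> float | None:
    """AUC as pairwise concordance: P(score_pos > score_neg), ties 1/2.

    Computed via midranks; returns ``None`` when either class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores, truth) -> np.ndarray:
    """Empirical ROC curve as (FPR, TPR) points, thresholds descending.

    Tied scores are collapsed into a single step so the curve is a function
    of the threshold; both coordinates are monotone non-decreasing and the
    curve runs from (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    # indices where a new (lower) threshold starts
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(t)[distinct]
    fps = np.cumsum(~t)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return np.column_stack([fpr, tpr])


def auc_trapezoid(points: np.ndarray) -> float:
    """Trapezoidal area under a (FPR, TPR) ROC polyline."""
    points = np.asarray(points, dtype=float)
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def evaluate_scores(scores, calls, truth, n_unclassifiable: int = 0) -> PerformanceReport:
    """Full performance report: confusion metrics from ``calls``, ROC and
    AUC from continuous ``scores``, both against the same ``truth``.

    AUC is the rank (pairwise-concordance) statistic; ``roc_points`` is
    attached for plotting/inspection and integrates to the same value.
    """
    report = confusion_metrics(calls, truth, n_unclassifiable=n_unclassifiable)
    truth_arr = np.asarray(truth, dtype=bool)
    if truth_arr.any() and not truth_arr.all():
        report.roc_points = roc_points(scores, truth_arr)
        report.auc = auc_rank(scores, truth_arr)
    return report
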