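"""Retrieval validation: threshold-sweep ROC against task-label ground truth.

Every window is used in turn as a query. Against each query, the other
windows are ranked by their Pearson correlation with it, and a predicted-
positive set {j != query : r_qj >= threshold} is formed for every threshold
on a fixed common grid (r in {-1, -0.99, ..., 1} by default). Ground-truth
positives are the windows sharing the query's condition label; the query
itself is excluded from its own candidates (its r = 1 would inflate TPR for
free). TPR = TP/(TP+FN) and FPR = FP/(FP+TN) are averaged across queries at
each fixed threshold, and the area under the averaged (FPR, TPR) curve —
with (0,0) and (1,1) appended — is computed by the trapezoid rule.

Queries whose label has no other member (no positives) or whose label covers
every other window (no negatives) are skipped with a warning, as are windows
with constant feature vectors (their correlations are undefined).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix
from .simindex import correlation_matrix

__all__ = [
    "ROCPoint",
    "ROCCurve",
    "default_thresholds",
    "pairwise_r_matrix",
    "roc_per_query",
    "averaged_roc",
]


def default_thresholds() -> np.ndarray:
    """The common correlation-threshold grid: -1 to 1 in steps of 0.01."""
    return np.round(np.arange(-1.0, 1.0 + 1e-9, 0.01), 2)


@dataclass(frozen=True)
class ROCPoint:
    """Confusion counts at one correlation threshold."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn)


@dataclass
class ROCCurve:
    """Averaged ROC over queries on a common threshold grid."""

    thresholds: np.ndarray
    fpr: np.ndarray  # mean FPR per threshold
    tpr: np.ndarray  # mean TPR per threshold
    auc: float
    n_queries: int


def pairwise_r_matrix(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Symmetric all-pairs window correlation matrix (NaN for constant rows)."""
    f = features.features if isinstance(features, FeatureMatrix) else features
    if f.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    return correlation_matrix(f)


def roc_per_query(
    r_row: np.ndarray,
    labels: list[str] | np.ndarray,
    query_index: int,
    thresholds: np.ndarray,
) -> list[ROCPoint] | None:
    """Threshold sweep for one query window.

    Candidates are all other windows with a defined correlation; positives
    are those sharing the query's label. Returns None (with a warning) when
    the sweep is undefined: no positives, no negatives, or a constant query
    window.
    """
    labels = np.asarray(labels)
    if len(labels) != len(r_row):
        raise ValueError("labels must cover all windows")
    candidates = np.ones(len(r_row), dtype=bool)
    candidates[query_index] = False
    candidates &= np.isfinite(r_row)
    positive = candidates & (labels == labels[query_index])
    negative = candidates & (labels != labels[query_index])
    n_pos = int(positive.sum())
    n_neg = int(negative.sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn(
            f"query {query_index}: no {'positives' if n_pos == 0 else 'negatives'} "
            "among candidates; skipped"
        )
        return None
    points = []
    for t in thresholds:
        pred = candidates & (r_row >= t)
        tp = int((pred & positive).sum())
        fp = int((pred & negative).sum())
        points.append(
            ROCPoint(threshold=float(t), tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp)
        )
    return points


def averaged_roc(
    r_matrix: np.ndarray,
    labels: list[str] | np.ndarray,
    thresholds: np.ndarray | None = None,
) -> ROCCurve:
    """Average per-query TPR/FPR threshold-wise and integrate the curve.

    Requires at least two distinct labels. The averaged (FPR, TPR) points are
    completed with (0,0) and (1,1) and integrated by the trapezoid rule.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 distinct labels")
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.sort(np.asarray(thresholds, dtype=np.float64))

    tprs, fprs = [], []
    for qi in range(len(labels)):
        points = roc_per_query(r_matrix[qi], labels, qi, thresholds)
        if points is None:
            continue
        tprs.append([p.tpr for p in points])
        fprs.append([p.fpr for p in points])
    if not tprs:
        raise ValueError("every query was skipped; ROC undefined")
    mean_tpr = np.mean(tprs, axis=0)
    mean_fpr = np.mean(fprs, axis=0)

    # high threshold -> (0,0); low -> (1,1). Sort by FPR ascending and anchor.
    fpr_curve = np.concatenate([[0.0], mean_fpr[::-1], [1.0]])
    tpr_curve = np.concatenate([[0.0], mean_tpr[::-1], [1.0]])
    order = np.argsort(fpr_curve, kind="stable")
    auc = float(np.trapezoid(tpr_curve[order], fpr_curve[order]))
    return ROCCurve(
        thresholds=thresholds,
        fpr=mean_fpr,
        tpr=mean_tpr,
        auc=auc,
        n_queries=len(tprs),
    )
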