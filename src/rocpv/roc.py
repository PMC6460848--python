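"""Empirical ROC curves, AUROC and operating-point statistics.

A subject is test-positive iff its score is greater than or equal to the
threshold (higher score = higher predicted risk).  The empirical ROC
curve places one operating point per distinct observed score plus the
(sn=0, sp=1) corner, so tied scores produce diagonal segments and the
trapezoidal area equals the Mann-Whitney rank statistic exactly.

Curves are stored in (x = 1 - specificity, y = sensitivity) coordinates;
user-facing reports carry both sn and sp to avoid axis confusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import LabeledScores
from .errors import UndefinedStatisticError

__all__ = [
    "ConfusionMatrix",
    "OperatingPoint",
    "RocCurve",
    "confusion_at_threshold",
    "sensitivity",
    "specificity",
    "empirical_roc",
    "auroc_trapezoid",
    "auroc_rank",
    "sensitivity_at_specificity",
    "read_roc_csv",
    "write_roc_csv",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 table of classification counts at a fixed threshold."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class OperatingPoint:
    """A (threshold, sensitivity, specificity) triple on a ROC curve.

    ``threshold`` may be +/-inf at the curve endpoints.
    """

    threshold: float
    sn: float
    sp: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.sn <= 1.0 and 0.0 <= self.sp <= 1.0):
            raise ValueError(f"sn/sp must lie in [0,1]: sn={self.sn}, sp={self.sp}")

    @property
    def fpr(self) -> float:
        return 1.0 - self.sp


class RocCurve:
    """An ordered empirical ROC curve from (sn=0, sp=1) to (sn=1, sp=0).

    Attributes
    ----------
    points : list of OperatingPoint
        Ordered by decreasing threshold; sensitivity and false positive
        rate are non-decreasing along the list.
    auroc : float
        Trapezoidal area under the piecewise-linear curve.
    """

    def __init__(self, points: Sequence[OperatingPoint]):
        points = list(points)
        if len(points) < 2:
            raise ValueError("a ROC curve needs at least two points")
        first, last = points[0], points[-1]
        if not (first.sn == 0.0 and first.sp == 1.0):
            raise ValueError("first point must be (sn=0, sp=1)")
        if not (last.sn == 1.0 and last.sp == 0.0):
            raise ValueError("last point must be (sn=1, sp=0)")
        fpr = np.array([p.fpr for p in points])
        tpr = np.array([p.sn for p in points])
        if np.any(np.diff(fpr) < -1e-12) or np.any(np.diff(tpr) < -1e-12):
            raise ValueError("sn and 1-sp must be non-decreasing along the curve")
        self.points = points
        self.fpr = fpr
        self.tpr = tpr
        self.thresholds = np.array([p.threshold for p in points])
        self.auroc = auroc_trapezoid(list(zip(fpr, tpr)))

    def __len__(self) -> int:
        return len(self.points)

    def __repr__(self) -> str:
        return f"RocCurve({len(self.points)} points, auroc={self.auroc:.4f})"

    @classmethod
    def from_fpr_tpr(
        cls, fpr: Sequence[float], tpr: Sequence[float], thresholds: Sequence[float] | None = None
    ) -> "RocCurve":
        """Build a curve from (fpr, tpr) arrays, adding corner points if absent."""
        fpr = list(map(float, fpr))
        tpr = list(map(float, tpr))
        if thresholds is None:
            thresholds = [np.nan] * len(fpr)
        thresholds = list(map(float, thresholds))
        if not (fpr[0] == 0.0 and tpr[0] == 0.0):
            fpr.insert(0, 0.0)
            tpr.insert(0, 0.0)
            thresholds.insert(0, np.inf)
        if not (fpr[-1] == 1.0 and tpr[-1] == 1.0):
            fpr.append(1.0)
            tpr.append(1.0)
            thresholds.append(-np.inf)
        pts = [
            OperatingPoint(t, y, 1.0 - x) for t, x, y in zip(thresholds, fpr, tpr)
        ]
        return cls(pts)


def confusion_at_threshold(data: LabeledScores, threshold: float) -> ConfusionMatrix:
    """Classification counts with test-positive defined as score >= threshold."""
    positive = data.scores >= threshold
    case = data.labels == 1
    tp = int(np.sum(positive & case))
    fp = int(np.sum(positive & ~case))
    fn = int(np.sum(~positive & case))
    tn = int(np.sum(~positive & ~case))
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(cm: ConfusionMatrix) -> float:
    """Sn = TP / (TP + FN), the true positive rate."""
    if cm.tp + cm.fn == 0:
        raise UndefinedStatisticError("sensitivity undefined: no cases present")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """Sp = TN / (TN + FP), the true negative rate."""
    if cm.tn + cm.fp == 0:
        raise UndefinedStatisticError("specificity undefined: no controls present")
    return cm.tn / (cm.tn + cm.fp)


def _roc_arrays(case_scores: np.ndarray, control_scores: np.ndarray):
    """Vectorised (fpr, tpr, thresholds) for the empirical curve.

    One entry per distinct observed score (positive iff score >= t), with
    the leading (0, 0) corner at threshold +inf.  Shared fast path for
    curve construction and bootstrap resampling.
    """
    n1 = case_scores.size
    n0 = control_scores.size
    scores = np.concatenate([case_scores, control_scores])
    labels = np.concatenate([np.ones(n1, dtype=bool), np.zeros(n0, dtype=bool)])
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    l = labels[order]
    # last index of each run of equal scores, descending
    distinct_last = np.flatnonzero(np.append(s[1:] != s[:-1], True))
    tp_cum = np.cumsum(l)
    tps = tp_cum[distinct_last]
    counts = distinct_last + 1
    fps = counts - tps
    tpr = np.concatenate([[0.0], tps / n1])
    fpr = np.concatenate([[0.0], fps / n0])
    thresholds = np.concatenate([[np.inf], s[distinct_last]])
    return fpr, tpr, thresholds


def empirical_roc(data: LabeledScores) -> RocCurve:
    """Empirical ROC curve with one operating point per distinct score.

    The threshold sweeps over every distinct observed value (positive iff
    score >= threshold); the (sn=0, sp=1) corner at threshold +inf is
    prepended and the lowest threshold yields the (sn=1, sp=0) corner.
    All scores identical is accepted: the curve degenerates to the
    diagonal chord (a non-discriminative test, AUROC = 0.5).
    """
    fpr, tpr, thr = _roc_arrays(data.case_scores, data.control_scores)
    pts = [
        OperatingPoint(float(t), float(y), float(1.0 - x))
        for t, x, y in zip(thr, fpr, tpr)
    ]
    return RocCurve(pts)


def auroc_trapezoid(points: Sequence[tuple[float, float]] | RocCurve) -> float:
    """Trapezoidal area under a piecewise-linear curve in (fpr, tpr) space."""
    if isinstance(points, RocCurve):
        x, y = points.fpr, points.tpr
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    return float(np.trapezoid(y, x))


def auroc_rank(data: LabeledScores) -> float:
    """AUROC as the Mann-Whitney rank statistic.

    Fraction of (case, control) pairs in which the case scores higher,
    tied pairs counted 1/2.  Equals the trapezoidal area under the
    empirical curve exactly, ties included.
    """
    r = rankdata(data.scores)
    n1 = data.n_cases
    n0 = data.n_controls
    r1 = r[data.labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _sn_at_fpr(fpr: np.ndarray, tpr: np.ndarray, x: np.ndarray | float) -> np.ndarray | float:
    """Linear interpolation of the curve's upper envelope at fpr = x.

    Where the curve is vertical (repeated fpr values) the highest
    attainable sensitivity is returned.
    """
    # keep max tpr per unique fpr -> upper envelope at vertical jumps
    ux, inverse = np.unique(fpr, return_inverse=True)
    uy = np.zeros_like(ux)
    np.maximum.at(uy, inverse, tpr)
    return np.interp(x, ux, uy)


def sensitivity_at_specificity(curve: RocCurve, sp_target: float) -> float:
    """Sensitivity of the curve at a fixed specificity.

    Linearly interpolates between adjacent empirical points; at a
    specificity attained over a vertical segment the highest sensitivity
    is reported.  sensitivity_at_specificity(curve, 0.0) is always 1.
    """
    if not 0.0 <= sp_target <= 1.0:
        raise ValueError("sp_target must lie in [0,1]")
    return float(_sn_at_fpr(curve.fpr, curve.tpr, 1.0 - sp_target))


def write_roc_csv(curve: RocCurve, path: str | Path) -> None:
    """Write a curve as CSV with columns threshold, sn, sp, fpr."""
    pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "sn": curve.tpr,
            "sp": 1.0 - curve.fpr,
            "fpr": curve.fpr,
        }
    ).to_csv(path, index=False)


def read_roc_csv(path: str | Path) -> RocCurve:
    """Read a curve written by :func:`write_roc_csv`."""
    df = pd.read_csv(path)
    return RocCurve.from_fpr_tpr(df["fpr"], df["sn"], df["threshold"])
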