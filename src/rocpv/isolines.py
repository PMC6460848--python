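"""Equi-PPV / equi-NPV isolines, clinical-relevance regions and ROC compliance.

Fixing a predictive-value target at a given prevalence traces a straight
line in ROC space (x = 1 - Sp, y = Sn):

    equi-PPV:  Sn = (1 - Sp) * ((1-p)/p) * (PPVc / (1 - PPVc))
               -- through (0, 0), slope ((1-p)/p) * PPVc/(1-PPVc)
    equi-NPV:  Sn = 1 - Sp * ((1-p)/p) * ((1 - NPVc) / NPVc)
               -- through (1, 1), slope ((1-p)/p) * (1-NPVc)/NPVc

Points above an isoline exceed the corresponding predictive-value
cutoff.  Combined with minimum sensitivity/specificity requirements the
isolines partition ROC space into clinical-relevance quadrants; a test
complies with the criteria iff its ROC curve enters the success region
(the intersection of all the half-planes, closed inequalities).

All geometry here is exact: the region is a convex polygon obtained by
half-plane clipping, and curve/region intersection is computed
analytically segment by segment on the piecewise-linear ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import numpy as np

from .bayes import Prevalence, _as_p, npv, ppv
from .errors import InfeasibleCriteriaError, InvalidPointError
from .roc import OperatingPoint, RocCurve

logger = logging.getLogger(__name__)

__all__ = [
    "PredictiveCriteria",
    "IsoLine",
    "SuccessRegion",
    "ComplianceReport",
    "specificity_for_ppv",
    "equi_ppv_line",
    "equi_npv_line",
    "success_region",
    "roc_meets_criteria",
    "lr_to_min_operating_point",
    "min_auroc_through_point",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PredictiveCriteria:
    """Prevalence-aware minimum performance requirements.

    At least one of ``ppv_c`` (rule-in) / ``npv_c`` (rule-out) must be
    given; ``sn_min`` / ``sp_min`` are optional companions.
    """

    p: Prevalence | float
    ppv_c: float | None = None
    npv_c: float | None = None
    sn_min: float | None = None
    sp_min: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", _as_p(self.p))
        if self.ppv_c is None and self.npv_c is None:
            raise ValueError("at least one of ppv_c / npv_c is required")
        for name, lo, hi in (
            ("ppv_c", 0.0, 1.0),
            ("npv_c", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if v is not None and not lo < v < hi:
                raise ValueError(f"{name} must lie strictly in ({lo},{hi}), got {v}")
        for name in ("sn_min", "sp_min"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")

    def rule_in_only(self) -> "PredictiveCriteria":
        return PredictiveCriteria(self.p, ppv_c=self.ppv_c, sn_min=self.sn_min)

    def rule_out_only(self) -> "PredictiveCriteria":
        return PredictiveCriteria(self.p, npv_c=self.npv_c, sp_min=self.sp_min)


@dataclass(frozen=True)
class IsoLine:
    """A constant-predictive-value line in (x = 1-Sp, y = Sn) coordinates.

    ``y = slope * x + intercept``, clipped to the unit square between
    ``start`` and ``end``.
    """

    kind: str  # "equi-ppv" | "equi-npv"
    slope: float
    intercept: float
    start: tuple[float, float]
    end: tuple[float, float]
    p: float
    cutoff: float

    def y_at(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def side(self, x, y) -> np.ndarray:
        """+1 above the line (predictive value exceeds the cutoff), -1 below, 0 on it."""
        return np.sign(np.asarray(y, dtype=float) - self.y_at(x))


# A half-plane a*x + b*y + c >= 0 in (x = 1-sp, y = sn) coordinates.
@dataclass(frozen=True)
class _Constraint:
    a: float
    b: float
    c: float
    name: str

    def value(self, x, y):
        return self.a * np.asarray(x, float) + self.b * np.asarray(y, float) + self.c


@dataclass(frozen=True)
class SuccessRegion:
    """Convex feasible region of ROC space where all criteria hold."""

    constraints: tuple[_Constraint, ...]
    vertices: tuple[tuple[float, float], ...]
    criteria: PredictiveCriteria

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0

    def contains(self, x, y, tol: float = 1e-9) -> np.ndarray:
        """Closed-region membership test (vectorised)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ok = (x >= -tol) & (x <= 1 + tol) & (y >= -tol) & (y <= 1 + tol)
        for con in self.constraints:
            ok &= con.value(x, y) >= -tol
        return ok


@dataclass(frozen=True)
class ComplianceReport:
    """Whether (and where) a ROC curve enters a success region."""

    meets: bool
    criteria: PredictiveCriteria
    crossings: tuple[tuple[float, float], ...]  # boundary crossing points (fpr, sn)
    segments_inside: tuple[tuple[tuple[float, float], tuple[float, float]], ...]
    best_ppv: float
    best_npv: float
    meets_rule_in: bool | None = None
    meets_rule_out: bool | None = None
    region: SuccessRegion = field(default=None, repr=False)


def specificity_for_ppv(sn: float, ppv_c: float, p: Prevalence | float) -> float:
    """Specificity required to reach PPV = ppv_c at sensitivity sn.

    Sp = 1 - Sn * (p/(1-p)) * ((1-PPVc)/PPVc).  A negative return value
    means no specificity can achieve this PPV at this sensitivity and
    prevalence; it is reported as-is, not clamped.
    """
    p = _as_p(p)
    if not 0.0 < ppv_c < 1.0:
        raise ValueError("ppv_c must lie strictly in (0,1)")
    return 1.0 - sn * (p / (1.0 - p)) * ((1.0 - ppv_c) / ppv_c)


def _clip_unit_square(slope: float, intercept: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Endpoints of y = slope*x + intercept clipped to the unit square."""
    pts = []
    for x in (0.0, 1.0):
        y = slope * x + intercept
        if -_EPS <= y <= 1 + _EPS:
            pts.append((x, min(max(y, 0.0), 1.0)))
    if slope != 0.0:
        for y in (0.0, 1.0):
            x = (y - intercept) / slope
            if -_EPS <= x <= 1 + _EPS:
                pts.append((min(max(x, 0.0), 1.0), y))
    if not pts:
        raise InfeasibleCriteriaError("isoline does not intersect the unit square")
    pts = sorted(set(pts))
    return pts[0], pts[-1]


def equi_ppv_line(ppv_c: float, p: Prevalence | float) -> IsoLine:
    """The line of constant PPV = ppv_c at prevalence p.

    Passes through the ROC origin with slope ((1-p)/p) * ppv_c/(1-ppv_c);
    every point strictly above it has PPV > ppv_c.  Lower prevalence or a
    higher cutoff steepens the line.
    """
    p = _as_p(p)
    if not 0.0 < ppv_c < 1.0:
        raise ValueError("ppv_c must lie strictly in (0,1)")
    slope = ((1.0 - p) / p) * (ppv_c / (1.0 - ppv_c))
    if ppv_c <= p:
        logger.warning(
            "PPV cutoff %.4g <= prevalence %.4g: the equi-PPV line lies on/below "
            "the diagonal, so even a useless test meets it",
            ppv_c,
            p,
        )
    start, end = _clip_unit_square(slope, 0.0)
    return IsoLine("equi-ppv", slope, 0.0, start, end, p, ppv_c)


def equi_npv_line(npv_c: float, p: Prevalence | float) -> IsoLine:
    """The line of constant NPV = npv_c at prevalence p.

    Passes through (1-sp=1, sn=1) with slope ((1-p)/p)*(1-npv_c)/npv_c in
    (x, y) coordinates; every point strictly above it has NPV > npv_c.
    """
    p = _as_p(p)
    if not 0.0 < npv_c < 1.0:
        raise ValueError("npv_c must lie strictly in (0,1)")
    slope = ((1.0 - p) / p) * ((1.0 - npv_c) / npv_c)
    intercept = 1.0 - slope
    if npv_c <= 1.0 - p:
        logger.warning(
            "NPV cutoff %.4g <= 1 - prevalence %.4g: the equi-NPV line lies "
            "on/below the diagonal, so even a useless test meets it",
            npv_c,
            p,
        )
    start, end = _clip_unit_square(slope, intercept)
    return IsoLine("equi-npv", slope, intercept, start, end, p, npv_c)


def _criteria_constraints(criteria: PredictiveCriteria) -> list[_Constraint]:
    cons: list[_Constraint] = []
    p = criteria.p
    if criteria.ppv_c is not None:
        line = equi_ppv_line(criteria.ppv_c, p)
        cons.append(_Constraint(-line.slope, 1.0, 0.0, f"ppv>={criteria.ppv_c}"))
    if criteria.npv_c is not None:
        line = equi_npv_line(criteria.npv_c, p)
        cons.append(_Constraint(-line.slope, 1.0, -line.intercept, f"npv>={criteria.npv_c}"))
    if criteria.sn_min is not None:
        cons.append(_Constraint(0.0, 1.0, -criteria.sn_min, f"sn>={criteria.sn_min}"))
    if criteria.sp_min is not None:
        # sp >= sp_min  <=>  x <= 1 - sp_min
        cons.append(_Constraint(-1.0, 0.0, 1.0 - criteria.sp_min, f"sp>={criteria.sp_min}"))
    return cons


def _clip_polygon(vertices: list[tuple[float, float]], con: _Constraint) -> list[tuple[float, float]]:
    """Sutherland-Hodgman clip of a convex polygon by a half-plane."""
    if not vertices:
        return []
    out: list[tuple[float, float]] = []
    n = len(vertices)
    for i in range(n):
        cur = vertices[i]
        nxt = vertices[(i + 1) % n]
        vc = con.a * cur[0] + con.b * cur[1] + con.c
        vn = con.a * nxt[0] + con.b * nxt[1] + con.c
        if vc >= -_EPS:
            out.append(cur)
        if (vc > _EPS and vn < -_EPS) or (vc < -_EPS and vn > _EPS):
            t = vc / (vc - vn)
            out.append((cur[0] + t * (nxt[0] - cur[0]), cur[1] + t * (nxt[1] - cur[1])))
    # drop near-duplicate consecutive vertices
    dedup: list[tuple[float, float]] = []
    for v in out:
        if not dedup or (abs(v[0] - dedup[-1][0]) > 1e-12 or abs(v[1] - dedup[-1][1]) > 1e-12):
            dedup.append(v)
    if len(dedup) > 1 and abs(dedup[0][0] - dedup[-1][0]) <= 1e-12 and abs(dedup[0][1] - dedup[-1][1]) <= 1e-12:
        dedup.pop()
    return dedup


def success_region(criteria: PredictiveCriteria) -> SuccessRegion:
    """Feasible region of ROC space where every stated criterion holds.

    The intersection of the closed half-planes above the equi-PPV and/or
    equi-NPV lines, above sn_min and left of 1 - sp_min, within the unit
    square.  An empty polygon is a legitimate outcome: the criteria are
    unattainable by any test at this prevalence.
    """
    cons = _criteria_constraints(criteria)
    verts: list[tuple[float, float]] = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]
    for con in cons:
        verts = _clip_polygon(verts, con)
        if not verts:
            break
    return SuccessRegion(tuple(cons), tuple(verts), criteria)


def _curve_region_intersection(
    fpr: np.ndarray, tpr: np.ndarray, cons: list[_Constraint]
):
    """Sub-segments of the piecewise-linear curve inside the closed region.

    For each curve segment, each half-plane constrains the parameter to an
    interval (constraint values are affine along the segment); the
    intersection of intervals gives the inside portion analytically.
    Returns (segments_inside, crossings).
    """
    segs: list[tuple[tuple[float, float], tuple[float, float]]] = []
    crossings: list[tuple[float, float]] = []
    tol = 1e-12
    for i in range(len(fpr) - 1):
        x0, y0, x1, y1 = fpr[i], tpr[i], fpr[i + 1], tpr[i + 1]
        lo, hi = 0.0, 1.0
        feasible = True
        for con in cons:
            v0 = con.a * x0 + con.b * y0 + con.c
            v1 = con.a * x1 + con.b * y1 + con.c
            if v0 < -tol and v1 < -tol:
                feasible = False
                break
            if abs(v1 - v0) <= tol:
                continue  # affine value ~constant and >= 0 somewhere => everywhere
            t = v0 / (v0 - v1)
            if v0 < v1:  # entering the half-plane at t
                lo = max(lo, t)
            else:  # leaving at t
                hi = min(hi, t)
        if not feasible or lo > hi + tol:
            continue
        pa = (x0 + lo * (x1 - x0), y0 + lo * (y1 - y0))
        pb = (x0 + hi * (x1 - x0), y0 + hi * (y1 - y0))
        segs.append((pa, pb))
        if lo > 0.0:
            crossings.append(pa)
        if hi < 1.0:
            crossings.append(pb)
    return segs, crossings


def _best_predictive_values(fpr: np.ndarray, tpr: np.ndarray, p: float) -> tuple[float, float]:
    """Max PPV and max NPV attained along the curve at prevalence p.

    Both predictive values are Moebius functions of the parameter along
    any line segment, hence monotone there: the maxima sit at vertices.
    Vertices where a value is undefined ((0,0) for PPV, (1,1) for NPV)
    are skipped.
    """
    sn = tpr
    sp = 1.0 - fpr
    with np.errstate(divide="ignore", invalid="ignore"):
        d_pos = sn * p + (1.0 - sp) * (1.0 - p)
        d_neg = (1.0 - sn) * p + sp * (1.0 - p)
        ppv_v = np.where(d_pos > 0, sn * p / np.where(d_pos > 0, d_pos, 1.0), np.nan)
        npv_v = np.where(d_neg > 0, sp * (1.0 - p) / np.where(d_neg > 0, d_neg, 1.0), np.nan)
    return float(np.nanmax(ppv_v)), float(np.nanmax(npv_v))


def roc_meets_criteria(
    curve: RocCurve,
    criteria: PredictiveCriteria,
    mode: str = "interpolated",
) -> ComplianceReport:
    """Test whether a ROC curve enters the success region of the criteria.

    ``mode="interpolated"`` (default) evaluates the piecewise-linear
    curve, so a compliant operating point may fall between empirical
    vertices (such thresholds are realisable by randomising between
    adjacent cutoffs); ``mode="vertices"`` restricts the check to the
    empirical operating points.  When both a PPV and an NPV cutoff are
    given, each criterion is additionally evaluated alone to support
    split rule-in / rule-out development.
    """
    if mode not in ("interpolated", "vertices"):
        raise ValueError("mode must be 'interpolated' or 'vertices'")
    region = success_region(criteria)
    cons = list(region.constraints)

    # The equi-PPV line passes through (0,0) and the equi-NPV line through
    # (1,1), but the predictive value is undefined at its own corner (no
    # test-positives at (0,0), no test-negatives at (1,1)): a curve
    # touching the region only in that single degenerate point does not
    # meaningfully meet the criterion.
    def _degenerate(pt) -> bool:
        x, y = pt
        if criteria.ppv_c is not None and abs(x) < _EPS and abs(y) < _EPS:
            return True
        if criteria.npv_c is not None and abs(x - 1) < _EPS and abs(y - 1) < _EPS:
            return True
        return False

    if mode == "vertices":
        inside = region.contains(curve.fpr, curve.tpr, tol=_EPS)
        idx = [
            i for i in np.flatnonzero(inside) if not _degenerate((curve.fpr[i], curve.tpr[i]))
        ]
        segs = tuple(
            ((curve.fpr[i], curve.tpr[i]), (curve.fpr[i], curve.tpr[i])) for i in idx
        )
        crossings: tuple = ()
        meets = len(idx) > 0
    else:
        seg_list, cross_list = _curve_region_intersection(curve.fpr, curve.tpr, cons)
        seg_list = [
            (a, b)
            for a, b in seg_list
            if not (np.hypot(b[0] - a[0], b[1] - a[1]) < _EPS and _degenerate(a))
        ]
        segs = tuple(seg_list)
        crossings = tuple(cross_list)
        meets = len(segs) > 0
    best_ppv, best_npv = _best_predictive_values(curve.fpr, curve.tpr, criteria.p)
    meets_in = meets_out = None
    if criteria.ppv_c is not None and criteria.npv_c is not None:
        meets_in = roc_meets_criteria(curve, criteria.rule_in_only(), mode=mode).meets
        meets_out = roc_meets_criteria(curve, criteria.rule_out_only(), mode=mode).meets
    return ComplianceReport(
        meets=meets,
        criteria=criteria,
        crossings=crossings,
        segments_inside=segs,
        best_ppv=best_ppv,
        best_npv=best_npv,
        meets_rule_in=meets_in,
        meets_rule_out=meets_out,
        region=region,
    )


def lr_to_min_operating_point(lr_pos_min: float, lr_neg_max: float) -> OperatingPoint:
    """Least demanding (Sn, Sp) meeting both likelihood-ratio bounds.

    Solves Sn = LR+ * (1 - Sp) and Sn = 1 - LR- * Sp simultaneously:
    the unique intersection of the two constraint boundaries,

        Sp = (LR+ - 1) / (LR+ - LR-),   Sn = LR+ * (1 - Sp).

    Requiring LR+ >= 10 together with LR- <= 0.2 for instance demands
    Sn ~ 0.82 and Sp ~ 0.92 at minimum.
    """
    if not lr_pos_min > 1.0:
        raise ValueError("lr_pos_min must exceed 1")
    if not 0.0 < lr_neg_max < 1.0:
        raise ValueError("lr_neg_max must lie strictly in (0,1)")
    sp = (lr_pos_min - 1.0) / (lr_pos_min - lr_neg_max)
    sn = lr_pos_min * (1.0 - sp)
    if not (0.0 <= sp <= 1.0 and 0.0 <= sn <= 1.0):
        raise InfeasibleCriteriaError(
            f"no operating point in the unit square meets LR+>={lr_pos_min}, LR-<={lr_neg_max}"
        )
    return OperatingPoint(threshold=math.nan, sn=sn, sp=sp)


def min_auroc_through_point(pt: OperatingPoint) -> float:
    """Smallest AUROC of a concave ROC curve through the given point.

    The minimising concave envelope is the two-segment polyline
    (0,0) -> (1-Sp, Sn) -> (1,1), whose area is (Sn + Sp)/2.  Any
    concave curve through the point lies on or above this envelope.
    """
    if pt.sn + pt.sp < 1.0:
        raise InvalidPointError("operating point lies below the chance diagonal")
    return (pt.sn + pt.sp) / 2.0
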