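"""Decision-threshold selection under predictive-value constraints.

Classical rules (Youden index, closest-to-(0,1) corner, fixed
specificity) weigh sensitivity and specificity without reference to
prevalence.  The constrained rules here instead require a minimum PPV
(rule-in) or NPV (rule-out) at a stated prevalence and, among compliant
thresholds, maximise the complementary detection statistic: sensitivity
for a rule-in test (identify as many future cases as possible), and
specificity for a rule-out test (clear as many non-cases as possible).
More detection at equal compliance is strictly better; this preference
is configurable via ``objective``.

All rules enumerate the empirical operating points of the data, i.e.
one candidate threshold per distinct observed score plus +inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes import Prevalence, _as_p, npv, ppv
from .data import LabeledScores
from .errors import SubjectAlignmentError
from .isolines import PredictiveCriteria, success_region
from .roc import RocCurve, empirical_roc

__all__ = [
    "ThresholdChoice",
    "JointClassification",
    "select_rule_in_threshold",
    "select_rule_out_threshold",
    "youden_threshold",
    "closest_corner_threshold",
    "fixed_specificity_threshold",
    "joint_rule_in_rule_out",
]


@dataclass(frozen=True)
class ThresholdChoice:
    """A selected decision threshold and its operating characteristics.

    ``feasible`` is False when no threshold satisfies the constraints; in
    that case the operating-point fields describe the closest achievable
    point (the empirical point with the smallest total constraint
    violation) rather than a compliant choice.
    """

    rule: str
    feasible: bool
    threshold: float
    sn: float
    sp: float
    ppv: float | None = None
    npv: float | None = None
    prevalence: float | None = None
    objective_value: float | None = None

    def as_dict(self) -> dict:
        return {
            "rule": self.rule,
            "feasible": self.feasible,
            "threshold": self.threshold,
            "sn": self.sn,
            "sp": self.sp,
            "ppv": self.ppv,
            "npv": self.npv,
            "prevalence": self.prevalence,
            "objective_value": self.objective_value,
        }


@dataclass(frozen=True)
class JointClassification:
    """Population split of a paired rule-in / rule-out strategy.

    Fractions of the intended-use population (reweighted to prevalence p,
    since case-control samples cannot give population fractions
    directly):

    - ``high_risk``: flagged by the rule-in test, not cleared by the
      rule-out test;
    - ``low_risk``: cleared by the rule-out test, not flagged;
    - ``conflict``: flagged high risk *and* cleared low risk by the two
      independent tests simultaneously;
    - ``unclassified``: neither flagged nor cleared — remains in the
      one-fits-all care pathway.

    ``sample_fractions`` carries the unweighted sample split alongside.
    """

    high_risk: float
    low_risk: float
    conflict: float
    unclassified: float
    prevalence: float
    sample_fractions: dict

    def as_dict(self) -> dict:
        return {
            "high_risk": self.high_risk,
            "low_risk": self.low_risk,
            "conflict": self.conflict,
            "unclassified": self.unclassified,
            "prevalence": self.prevalence,
            "sample_fractions": dict(self.sample_fractions),
        }


def _operating_points(data: LabeledScores, curve: RocCurve | None = None):
    curve = curve if curve is not None else empirical_roc(data)
    return curve.thresholds, curve.tpr, 1.0 - curve.fpr


def _choice(rule, feasible, t, sn, sp, p=None, objective=None) -> ThresholdChoice:
    kw = {}
    if p is not None:
        p = _as_p(p)
        # PPV undefined only at (sn=0, sp=1), the +inf corner
        denom_pos = sn * p + (1 - sp) * (1 - p)
        denom_neg = (1 - sn) * p + sp * (1 - p)
        kw["ppv"] = ppv(sn, sp, p) if denom_pos > 0 else None
        kw["npv"] = npv(sn, sp, p) if denom_neg > 0 else None
        kw["prevalence"] = p
    return ThresholdChoice(
        rule=rule,
        feasible=feasible,
        threshold=float(t),
        sn=float(sn),
        sp=float(sp),
        objective_value=objective,
        **kw,
    )


def _closest_achievable(thr, sn, sp, region) -> int:
    """Index of the empirical point with least total constraint violation."""
    x = 1.0 - sp
    viol = np.zeros_like(sn)
    for con in region.constraints:
        viol += np.maximum(0.0, -(con.a * x + con.b * sn + con.c))
    return int(np.argmin(viol))


def select_rule_in_threshold(
    data: LabeledScores, criteria: PredictiveCriteria, objective: str = "sn"
) -> ThresholdChoice:
    """Best threshold for a rule-in test: PPV >= ppv_c (and Sn >= sn_min).

    Among compliant empirical thresholds, maximises sensitivity
    (tie-break: higher specificity).  ``objective="youden"`` switches the
    preference to Sn + Sp - 1.  Returns an infeasible result describing
    the closest achievable point when no threshold complies.
    """
    if criteria.ppv_c is None:
        raise ValueError("rule-in selection requires a PPV cutoff")
    crit = criteria.rule_in_only()
    return _select_constrained(data, crit, "rule-in", objective)


def select_rule_out_threshold(
    data: LabeledScores, criteria: PredictiveCriteria, objective: str = "sp"
) -> ThresholdChoice:
    """Best threshold for a rule-out test: NPV >= npv_c (and Sp >= sp_min).

    Mirror of :func:`select_rule_in_threshold`, maximising specificity
    (tie-break: higher sensitivity).
    """
    if criteria.npv_c is None:
        raise ValueError("rule-out selection requires an NPV cutoff")
    crit = criteria.rule_out_only()
    return _select_constrained(data, crit, "rule-out", objective)


def _select_constrained(data, criteria, rule, objective) -> ThresholdChoice:
    thr, sn, sp = _operating_points(data)
    region = success_region(criteria)
    ok = region.contains(1.0 - sp, sn, tol=1e-12)
    p = criteria.p
    if objective == "sn":
        primary, secondary = sn, sp
    elif objective == "sp":
        primary, secondary = sp, sn
    elif objective == "youden":
        primary, secondary = sn + sp, np.zeros_like(sn)
    else:
        raise ValueError(f"unknown objective {objective!r}")
    if not ok.any():
        i = _closest_achievable(thr, sn, sp, region)
        return _choice(rule, False, thr[i], sn[i], sp[i], p, objective=None)
    idx = np.flatnonzero(ok)
    best = idx[np.lexsort((secondary[idx], primary[idx]))[-1]]
    return _choice(
        rule, True, thr[best], sn[best], sp[best], p, objective=float(primary[best])
    )


def youden_threshold(data: LabeledScores, p: Prevalence | float | None = None) -> ThresholdChoice:
    """Threshold maximising the Youden index J = Sn + Sp - 1.

    Prevalence-blind; ties broken towards the smallest threshold.  If a
    prevalence is supplied, the achieved PPV/NPV at that prevalence are
    reported alongside.
    """
    thr, sn, sp = _operating_points(data)
    j = sn + sp - 1.0
    best = _argbest_smallest_threshold(j, thr)
    return _choice("youden", True, thr[best], sn[best], sp[best], p, objective=float(j[best]))


def closest_corner_threshold(
    data: LabeledScores, p: Prevalence | float | None = None
) -> ThresholdChoice:
    """Threshold minimising the distance to the perfect-test corner (0, 1).

    Distance sqrt((1-Sp)^2 + (1-Sn)^2); ties broken towards the smallest
    threshold.  Prevalence-blind like the Youden rule.
    """
    thr, sn, sp = _operating_points(data)
    d = np.hypot(1.0 - sp, 1.0 - sn)
    best = _argbest_smallest_threshold(-d, thr)
    return _choice("closest-corner", True, thr[best], sn[best], sp[best], p, objective=float(d[best]))


def fixed_specificity_threshold(
    data: LabeledScores, sp_min: float, p: Prevalence | float | None = None
) -> ThresholdChoice:
    """Lock the false positive rate: maximise Sn subject to Sp >= sp_min."""
    thr, sn, sp = _operating_points(data)
    ok = sp >= sp_min - 1e-12
    idx = np.flatnonzero(ok)
    best = idx[np.lexsort((sp[idx], sn[idx]))[-1]]
    return _choice("fixed-specificity", True, thr[best], sn[best], sp[best], p, objective=float(sn[best]))


def _argbest_smallest_threshold(score: np.ndarray, thr: np.ndarray) -> int:
    """Index of max score; among ties, the smallest threshold."""
    m = score.max()
    tied = np.flatnonzero(score >= m - 1e-12)
    return int(tied[np.argmin(thr[tied])])


def joint_rule_in_rule_out(
    labels: np.ndarray,
    scores_in: np.ndarray,
    threshold_in: float,
    scores_out: np.ndarray,
    threshold_out: float,
    p: Prevalence | float,
) -> JointClassification:
    """Population split of two independent tests applied to the same subjects.

    The rule-in test flags a subject high-risk iff its rule-in score is
    >= threshold_in; the rule-out test clears a subject (low-risk) iff
    its rule-out score is < threshold_out.  The four joint categories are
    computed per label stratum and reweighted to prevalence p (the
    case-control sample fractions cannot be used directly).
    """
    labels = np.asarray(labels)
    scores_in = np.asarray(scores_in, dtype=float)
    scores_out = np.asarray(scores_out, dtype=float)
    if not (labels.shape == scores_in.shape == scores_out.shape):
        raise SubjectAlignmentError("labels and both score vectors must have equal length")
    p = _as_p(p)
    flagged = scores_in >= threshold_in
    cleared = scores_out < threshold_out

    def stratum_rates(mask: np.ndarray) -> np.ndarray:
        n = mask.sum()
        if n == 0:
            raise SubjectAlignmentError("a label stratum is empty")
        f, c = flagged[mask], cleared[mask]
        return np.array(
            [
                np.sum(f & ~c),  # high-risk only
                np.sum(~f & c),  # low-risk only
                np.sum(f & c),  # conflict
                np.sum(~f & ~c),  # unclassified
            ]
        ) / n

    rates_case = stratum_rates(labels == 1)
    rates_ctrl = stratum_rates(labels == 0)
    weighted = p * rates_case + (1.0 - p) * rates_ctrl
    sample = (labels == 1).mean() * rates_case + (labels == 0).mean() * rates_ctrl
    return JointClassification(
        high_risk=float(weighted[0]),
        low_risk=float(weighted[1]),
        conflict=float(weighted[2]),
        unclassified=float(weighted[3]),
        prevalence=p,
        sample_fractions={
            "high_risk": float(sample[0]),
            "low_risk": float(sample[1]),
            "conflict": float(sample[2]),
            "unclassified": float(sample[3]),
        },
    )
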