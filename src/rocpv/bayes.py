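"""Bayes-theorem conversions between test accuracy and predictive values.

Links the prevalence-free description of a test (sensitivity,
specificity, likelihood ratios) to its prevalence-dependent clinical
performance (PPV, NPV, "1 in N" risk notation):

    PPV = Sn p / (Sn p + (1 - Sp)(1 - p))
    NPV = Sp (1 - p) / ((1 - Sn) p + Sp (1 - p))

with p the pre-test probability (prevalence) in the intended-use
population.  Equivalently, the reciprocal predictive values are linear
in the likelihood ratios:

    1/PPV = 1 + ((1 - p)/p) / LR+        LR+ = Sn / (1 - Sp)
    1/NPV = 1 + (p/(1 - p)) * LR-        LR- = (1 - Sn) / Sp

Prevalence is always an explicit input.  It is never estimated from the
sample, because case-control designs fix the case fraction by design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import InvalidRiskError, UndefinedStatisticError

__all__ = [
    "Prevalence",
    "LikelihoodRatios",
    "PredictiveValues",
    "ppv",
    "npv",
    "predictive_values",
    "likelihood_ratios",
    "inverse_ppv_linear",
    "inverse_npv_linear",
    "parse_risk",
    "risk_to_probability",
    "probability_to_risk",
    "risk_to_npv",
]


@dataclass(frozen=True)
class Prevalence:
    """Pre-test probability of the condition, strictly inside (0, 1)."""

    p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"prevalence must lie strictly in (0,1), got {self.p}")

    @property
    def odds(self) -> float:
        """Prior odds p / (1 - p)."""
        return self.p / (1.0 - self.p)

    def __float__(self) -> float:
        return self.p


def _as_p(p: "Prevalence | float") -> float:
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"prevalence must lie strictly in (0,1), got {p}")
    return p


@dataclass(frozen=True)
class LikelihoodRatios:
    """Positive and negative likelihood ratios of a dichotomised test."""

    lr_pos: float
    lr_neg: float


@dataclass(frozen=True)
class PredictiveValues:
    ppv: float
    npv: float


def ppv(sn, sp, p: Prevalence | float):
    """Positive predictive value at prevalence p (Bayes' theorem).

    Accepts scalars or numpy arrays for ``sn``/``sp``.  Undefined when no
    subject can test positive (sn = 0 and sp = 1).
    """
    p = _as_p(p)
    sn = np.asarray(sn, dtype=float)
    sp = np.asarray(sp, dtype=float)
    denom = sn * p + (1.0 - sp) * (1.0 - p)
    if np.any(denom == 0.0):
        raise UndefinedStatisticError("PPV undefined: no test-positives possible (sn=0, sp=1)")
    out = sn * p / denom
    return float(out) if out.ndim == 0 else out


def npv(sn, sp, p: Prevalence | float):
    """Negative predictive value at prevalence p (Bayes' theorem).

    Undefined when no subject can test negative (sn = 1 and sp = 0).
    """
    p = _as_p(p)
    sn = np.asarray(sn, dtype=float)
    sp = np.asarray(sp, dtype=float)
    denom = (1.0 - sn) * p + sp * (1.0 - p)
    if np.any(denom == 0.0):
        raise UndefinedStatisticError("NPV undefined: no test-negatives possible (sn=1, sp=0)")
    out = sp * (1.0 - p) / denom
    return float(out) if out.ndim == 0 else out


def predictive_values(sn: float, sp: float, p: Prevalence | float) -> PredictiveValues:
    """Both predictive values at once."""
    return PredictiveValues(ppv=ppv(sn, sp, p), npv=npv(sn, sp, p))


def likelihood_ratios(sn: float, sp: float) -> LikelihoodRatios:
    """LR+ = Sn/(1-Sp) and LR- = (1-Sn)/Sp.

    LR+ is +inf for a perfectly specific test; LR- is undefined for a
    test with zero specificity.
    """
    lr_pos = np.inf if sp == 1.0 else sn / (1.0 - sp)
    if sp == 0.0:
        raise UndefinedStatisticError("LR- undefined at specificity 0")
    lr_neg = (1.0 - sn) / sp
    return LikelihoodRatios(lr_pos=float(lr_pos), lr_neg=float(lr_neg))


def inverse_ppv_linear(lr_pos: float, p: Prevalence | float) -> float:
    """Reciprocal PPV as a linear function of the reciprocal LR+.

    1/PPV = 1 + ((1 - p)/p) / LR+; consistent with :func:`ppv` whenever
    LR+ = Sn/(1-Sp).
    """
    p = _as_p(p)
    if lr_pos <= 0:
        raise ValueError("lr_pos must be positive")
    return 1.0 + ((1.0 - p) / p) / lr_pos


def inverse_npv_linear(lr_neg: float, p: Prevalence | float) -> float:
    """Reciprocal NPV as a linear function of LR-.

    1/NPV = 1 + (p/(1 - p)) * LR-; consistent with :func:`npv` whenever
    LR- = (1-Sn)/Sp.
    """
    p = _as_p(p)
    if lr_neg < 0:
        raise ValueError("lr_neg must be non-negative")
    return 1.0 + (p / (1.0 - p)) * lr_neg


_RISK_RE = re.compile(r"^\s*1\s*in\s*([0-9]*\.?[0-9]+)\s*$", re.IGNORECASE)


def parse_risk(risk: str | float) -> float:
    """Parse a risk given as '1 in N' (case-insensitive) or a probability.

    Returns the probability 1/N.  Plain numbers in (0, 1) are accepted as
    probabilities directly.
    """
    if isinstance(risk, str):
        m = _RISK_RE.match(risk)
        if m:
            return risk_to_probability(float(m.group(1)))
        try:
            value = float(risk)
        except ValueError as exc:
            raise InvalidRiskError(f"cannot parse risk {risk!r}") from exc
    else:
        value = float(risk)
    if not 0.0 < value < 1.0:
        raise InvalidRiskError(f"risk probability must lie in (0,1), got {value}")
    return value


def risk_to_probability(n: float) -> float:
    """'1 in N' -> probability 1/N."""
    if n <= 1.0:
        raise InvalidRiskError(f"'1 in N' requires N > 1, got {n}")
    return 1.0 / n


def probability_to_risk(probability: float) -> float:
    """Probability -> N of '1 in N'."""
    if not 0.0 < probability < 1.0:
        raise InvalidRiskError(f"probability must lie in (0,1), got {probability}")
    return 1.0 / probability


def risk_to_npv(n: float) -> float:
    """Residual risk '1 in N' among test-negatives -> NPV = 1 - 1/N."""
    return 1.0 - risk_to_probability(n)
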