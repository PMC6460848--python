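"""Synthetic risk-score generation with controllable ROC shape.

Scores are drawn from Gaussian mixtures: controls follow a standard
normal reference by default, and either class may contain a far-shifted
"well-discriminated" component.  That family is the simplest one that
realises the clinically important phenomenon that equal-AUROC tests can
differ sharply in rule-in or rule-out utility:

- a *rule-in-shaped* test has a fraction of cases that are almost
  perfectly separated from the tight control distribution (steep early
  ROC, favourable PPV);
- a *rule-out-shaped* test has a fraction of controls almost perfectly
  separated below the case distribution (late-rising ROC, favourable
  NPV);
- a *symmetric* test is the equal-variance binormal model.

For normal mixtures the population AUROC has the closed form
sum_ij w_i v_j * Phi((mu_i - nu_j) / sqrt(s_i^2 + t_j^2)), used as the
analytic oracle for the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

from .bayes import Prevalence, _as_p
from .data import LabeledScores
from .errors import InfeasibleCriteriaError

__all__ = [
    "Component",
    "GeneratorSpec",
    "generate",
    "analytic_auroc",
    "equal_auc_trio",
    "prevalence_weighted_population",
    "binormal_spec",
    "rule_in_spec",
    "rule_out_spec",
]

# location of the far-shifted, well-discriminated mixture component, in
# control standard deviations; far enough that its members are separated
# essentially perfectly (Phi(5/sqrt(2)) ~ 0.9998)
WELL_SEPARATED_SHIFT = 5.0


@dataclass(frozen=True)
class Component:
    """One Gaussian mixture component: (weight, loc, scale)."""

    weight: float
    loc: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("component weight must lie in [0,1]")
        if self.scale <= 0:
            raise ValueError("component scale must be positive")


@dataclass(frozen=True)
class GeneratorSpec:
    """Score distributions and sample sizes for one synthetic test.

    ``cases`` and ``controls`` are Gaussian mixtures whose weights must
    each sum to 1.  The default control distribution is the standard
    normal reference.
    """

    cases: tuple[Component, ...]
    controls: tuple[Component, ...] = (Component(1.0, 0.0, 1.0),)
    n_cases: int = 1000
    n_controls: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("cases", "controls"):
            comps = tuple(getattr(self, name))
            object.__setattr__(self, name, comps)
            if not comps:
                raise ValueError(f"{name} needs at least one component")
            total = sum(c.weight for c in comps)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must sum to 1, got {total}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("sample sizes must be >= 1")


def binormal_spec(shift: float, n_cases: int = 1000, n_controls: int = 1000,
                  seed: int | None = None, scale: float = 1.0) -> GeneratorSpec:
    """Equal-variance binormal model: cases N(shift, scale), controls N(0, scale)."""
    return GeneratorSpec(
        cases=(Component(1.0, shift, scale),),
        controls=(Component(1.0, 0.0, scale),),
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
    )


def _sample_mixture(rng: np.random.Generator, comps, n: int) -> np.ndarray:
    weights = np.array([c.weight for c in comps])
    which = rng.choice(len(comps), size=n, p=weights)
    z = rng.standard_normal(n)
    locs = np.array([c.loc for c in comps])
    scales = np.array([c.scale for c in comps])
    return locs[which] + scales[which] * z


def generate(spec: GeneratorSpec) -> LabeledScores:
    """Draw a case-control sample from the spec, reproducibly given its seed."""
    rng = np.random.default_rng(spec.seed)
    case_scores = _sample_mixture(rng, spec.cases, spec.n_cases)
    ctrl_scores = _sample_mixture(rng, spec.controls, spec.n_controls)
    scores = np.concatenate([case_scores, ctrl_scores])
    labels = np.concatenate(
        [np.ones(spec.n_cases, dtype=int), np.zeros(spec.n_controls, dtype=int)]
    )
    return LabeledScores(scores, labels)


def analytic_auroc(spec: GeneratorSpec) -> float:
    """Population AUROC P(case score > control score), closed form.

    For Gaussian mixtures the pair probability decomposes over component
    pairs: each contributes Phi((mu_i - nu_j)/sqrt(s_i^2 + t_j^2)).
    """
    total = 0.0
    for ci in spec.cases:
        for cj in spec.controls:
            sd = np.hypot(ci.scale, cj.scale)
            total += ci.weight * cj.weight * norm.cdf((ci.loc - cj.loc) / sd)
    return float(total)


def _solve_mixture_weight(target_auc: float, shift: float) -> float:
    """Weight f of the far component so that the mixture AUROC hits target.

    Mixing a well-separated component (pairwise AUROC Phi(shift/sqrt 2))
    with a chance component (0.5) gives AUROC affine in f; solved by
    bisection to 1e-4 on the analytic value.
    """
    hi_auc = float(norm.cdf(shift / np.sqrt(2.0)))
    if not 0.5 < target_auc <= hi_auc:
        raise InfeasibleCriteriaError(
            f"target AUROC {target_auc} outside achievable range (0.5, {hi_auc:.4f}] "
            f"for shift {shift}"
        )

    def auc_of(f: float) -> float:
        return f * hi_auc + (1.0 - f) * 0.5

    lo, hi = 0.0, 1.0
    while hi - lo > 1e-12:
        mid = (lo + hi) / 2.0
        if auc_of(mid) < target_auc:
            lo = mid
        else:
            hi = mid
    f = (lo + hi) / 2.0
    assert abs(auc_of(f) - target_auc) < 1e-4
    return f


def rule_in_spec(target_auc: float, n_cases: int = 1000, n_controls: int = 1000,
                 seed: int | None = None, shift: float = WELL_SEPARATED_SHIFT) -> GeneratorSpec:
    """Case-mixture spec: a fraction of cases is almost perfectly discriminated.

    Steep-early ROC, favourable for rule-in (PPV) criteria.
    """
    f = _solve_mixture_weight(target_auc, shift)
    return GeneratorSpec(
        cases=(Component(f, shift, 1.0), Component(1.0 - f, 0.0, 1.0)),
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
    )


def rule_out_spec(target_auc: float, n_cases: int = 1000, n_controls: int = 1000,
                  seed: int | None = None, shift: float = WELL_SEPARATED_SHIFT) -> GeneratorSpec:
    """Control-mixture spec: a fraction of controls is almost perfectly discriminated.

    Late-rising ROC, favourable for rule-out (NPV) criteria.
    """
    f = _solve_mixture_weight(target_auc, shift)
    return GeneratorSpec(
        cases=(Component(1.0, 0.0, 1.0),),
        controls=(Component(f, -shift, 1.0), Component(1.0 - f, 0.0, 1.0)),
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
    )


class Trio(NamedTuple):
    """Three equal-AUROC tests of different shape, with their samples."""

    symmetric: tuple[GeneratorSpec, LabeledScores]
    rule_in: tuple[GeneratorSpec, LabeledScores]
    rule_out: tuple[GeneratorSpec, LabeledScores]


def equal_auc_trio(target_auc: float, n_per_group: int = 1000, seed: int | None = None) -> Trio:
    """Three tests with the same population AUROC but different ROC shapes.

    (a) equal-variance binormal (shift sqrt(2) * Phi^-1(target)),
    (b) rule-in-shaped case mixture, (c) rule-out-shaped control mixture;
    mixture weights solved so each analytic AUROC equals ``target_auc``.
    Each member gets an independent child seed derived from ``seed``.
    """
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target_auc must lie strictly in (0.5, 1)")
    seeds = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    shift = float(np.sqrt(2.0) * norm.ppf(target_auc))
    sym = binormal_spec(shift, n_per_group, n_per_group, seed=int(seeds[0]))
    rin = rule_in_spec(target_auc, n_per_group, n_per_group, seed=int(seeds[1]))
    rout = rule_out_spec(target_auc, n_per_group, n_per_group, seed=int(seeds[2]))
    return Trio(
        symmetric=(sym, generate(sym)),
        rule_in=(rin, generate(rin)),
        rule_out=(rout, generate(rout)),
    )


def prevalence_weighted_population(
    spec: GeneratorSpec, p: Prevalence | float, n: int, seed: int | None = None
) -> LabeledScores:
    """Cohort-design sample: labels Bernoulli(p), scores from the class mixtures.

    Unlike the case-control sampler, the case fraction here *is* an
    estimate of prevalence, so empirical predictive values on this sample
    can be compared directly with the Bayes formulas.
    """
    p = _as_p(p)
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < p).astype(int)
    n1 = int(labels.sum())
    scores = np.empty(n)
    scores[labels == 1] = _sample_mixture(rng, spec.cases, n1)
    scores[labels == 0] = _sample_mixture(rng, spec.controls, n - n1)
    return LabeledScores(scores, labels)
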