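"""Bootstrap confidence bands for ROC curves and compliance with uncertainty.

Resampling is stratified: cases and controls are resampled separately
with their sample sizes preserved, because the case-control design fixes
the group sizes — pooled resampling would inject prevalence noise that
the design excludes.  Bands are pointwise percentile intervals of
sensitivity on a fixed specificity grid; every replicate is fully
determined by the seed.

The compliance verdict with uncertainty is three-valued: a test is
"compliant" when even the lower band edge enters the success region,
"potentially compliant" when only the point estimate or the upper edge
does, "non-compliant" otherwise.  The fraction of replicate curves that
individually meet the criteria is reported alongside, since the band
edge and the replicate curves are two different readings of what a
confidence region crossing the zone of success means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import LabeledScores
from .isolines import ComplianceReport, PredictiveCriteria, roc_meets_criteria, success_region, _curve_region_intersection
from .roc import RocCurve, _roc_arrays, _sn_at_fpr, empirical_roc

logger = logging.getLogger(__name__)

__all__ = ["BootstrapBand", "bootstrap_roc", "compliance_with_ci", "ComplianceWithCI"]

DEFAULT_B = 2000
DEFAULT_LEVEL = 0.95
DEFAULT_GRID = 101


@dataclass(frozen=True)
class BootstrapBand:
    """Pointwise percentile confidence band for sensitivity at specificity."""

    sp_grid: np.ndarray
    sn_lower: np.ndarray
    sn_point: np.ndarray
    sn_upper: np.ndarray
    n_boot: int
    level: float
    seed: int | None

    def __post_init__(self) -> None:
        if np.any(self.sn_lower > self.sn_point + 1e-12) or np.any(
            self.sn_point > self.sn_upper + 1e-12
        ):
            raise ValueError("band must bracket the point estimate")

    def width(self) -> np.ndarray:
        return self.sn_upper - self.sn_lower


@dataclass(frozen=True)
class ComplianceWithCI:
    """Three-valued compliance verdict with bootstrap support."""

    verdict: str  # "compliant" | "potentially compliant" | "non-compliant"
    point_report: ComplianceReport
    replicate_fraction: float
    band: BootstrapBand
    lower_meets: bool
    point_meets: bool
    upper_meets: bool


def _resample_sn_grid(rng, case_scores, control_scores, x_grid):
    """One stratified replicate's sensitivity at the fpr grid."""
    cs = rng.choice(case_scores, size=case_scores.size, replace=True)
    ns = rng.choice(control_scores, size=control_scores.size, replace=True)
    fpr, tpr, _ = _roc_arrays(cs, ns)
    return _sn_at_fpr(fpr, tpr, x_grid), fpr, tpr


def bootstrap_roc(
    data: LabeledScores,
    n_boot: int = DEFAULT_B,
    level: float = DEFAULT_LEVEL,
    seed: int | None = None,
    sp_grid: np.ndarray | None = None,
) -> BootstrapBand:
    """Pointwise percentile band for the empirical ROC curve.

    Cases and controls are resampled separately (sizes preserved); each
    replicate's sensitivity is read off at the specificity grid by linear
    interpolation and the band is formed from the (1-level)/2 and
    1-(1-level)/2 quantiles.  level -> 0 collapses the band onto the
    bootstrap median.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0,1)")
    if min(data.n_cases, data.n_controls) < 5:
        raise ValueError("bootstrap needs at least 5 subjects per class")
    if min(data.n_cases, data.n_controls) < 20:
        logger.warning(
            "fewer than 20 subjects in a class (%d cases / %d controls): "
            "percentile bands may be unreliable",
            data.n_cases,
            data.n_controls,
        )
    if sp_grid is None:
        sp_grid = np.linspace(0.0, 1.0, DEFAULT_GRID)
    sp_grid = np.asarray(sp_grid, dtype=float)
    x_grid = 1.0 - sp_grid
    rng = np.random.default_rng(seed)
    cases = data.case_scores
    controls = data.control_scores
    sn_reps = np.empty((n_boot, x_grid.size))
    for b in range(n_boot):
        sn_reps[b], _, _ = _resample_sn_grid(rng, cases, controls, x_grid)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(sn_reps, alpha, axis=0)
    upper = np.quantile(sn_reps, 1.0 - alpha, axis=0)
    curve = empirical_roc(data)
    point = _sn_at_fpr(curve.fpr, curve.tpr, x_grid)
    # percentile quantiles can sit a hair off the point estimate; the band
    # must bracket it by construction of the verdict logic
    lower = np.minimum(lower, point)
    upper = np.maximum(upper, point)
    return BootstrapBand(
        sp_grid=sp_grid,
        sn_lower=lower,
        sn_point=np.asarray(point, dtype=float),
        sn_upper=upper,
        n_boot=n_boot,
        level=level,
        seed=seed,
    )


def _band_edge_meets(sp_grid, sn_edge, criteria) -> bool:
    """Does the polyline through the band edge enter the success region?"""
    order = np.argsort(1.0 - sp_grid)
    x = (1.0 - sp_grid)[order]
    y = np.asarray(sn_edge)[order]
    region = success_region(criteria)
    segs, _ = _curve_region_intersection(x, y, list(region.constraints))
    return len(segs) > 0


def compliance_with_ci(
    data: LabeledScores,
    criteria: PredictiveCriteria,
    n_boot: int = DEFAULT_B,
    level: float = DEFAULT_LEVEL,
    seed: int | None = None,
    sp_grid: np.ndarray | None = None,
) -> ComplianceWithCI:
    """Compliance testing with bootstrap uncertainty.

    Replicate curves (not the gridded band) are used for the replicate
    fraction, so that fraction does not depend on the grid density.
    """
    if sp_grid is None:
        sp_grid = np.linspace(0.0, 1.0, DEFAULT_GRID)
    sp_grid = np.asarray(sp_grid, dtype=float)
    x_grid = 1.0 - sp_grid
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    cases = data.case_scores
    controls = data.control_scores
    region = success_region(criteria)
    cons = list(region.constraints)
    sn_reps = np.empty((n_boot, x_grid.size))
    n_meets = 0
    for b in range(n_boot):
        sn_reps[b], fpr, tpr = _resample_sn_grid(rng, cases, controls, x_grid)
        segs, _ = _curve_region_intersection(fpr, tpr, cons)
        n_meets += bool(segs)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(sn_reps, alpha, axis=0)
    upper = np.quantile(sn_reps, 1.0 - alpha, axis=0)
    curve = empirical_roc(data)
    point = _sn_at_fpr(curve.fpr, curve.tpr, x_grid)
    lower = np.minimum(lower, point)
    upper = np.maximum(upper, point)
    band = BootstrapBand(sp_grid, lower, np.asarray(point, float), upper, n_boot, level, seed)
    point_report = roc_meets_criteria(curve, criteria)
    lower_meets = _band_edge_meets(sp_grid, lower, criteria)
    point_meets = point_report.meets
    upper_meets = _band_edge_meets(sp_grid, upper, criteria)
    if lower_meets:
        verdict = "compliant"
    elif point_meets or upper_meets:
        verdict = "potentially compliant"
    else:
        verdict = "non-compliant"
    return ComplianceWithCI(
        verdict=verdict,
        point_report=point_report,
        replicate_fraction=n_meets / n_boot,
        band=band,
        lower_meets=lower_meets,
        point_meets=point_meets,
        upper_meets=upper_meets,
    )
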