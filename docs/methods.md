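# Methods

## Model and scope

`rocpv` evaluates a continuous risk score against binary outcomes under
the case-control paradigm: the investigator fixes the numbers of cases
and controls, so the sample case fraction carries no information about
disease prevalence. Prevalence *p* is therefore always an explicit user
input (the intended-use population's pre-test probability), and every
prevalence-dependent quantity — PPV, NPV, isolines, success regions,
population fractions — is parameterised by it. The score's orientation
is fixed throughout: higher score = higher predicted risk, and a subject
is test-positive iff score ≥ threshold (weak inequality). The paper-side
convention had to be chosen once for reproducible confusion matrices.

## Empirical ROC curves

The empirical curve places one operating point per distinct observed
score value, plus the (Sn = 0, Sp = 1) corner at threshold +∞; the
lowest observed threshold yields (Sn = 1, Sp = 0). Tied scores collapse
into a single vertex, so ties produce diagonal segments and the
trapezoidal area under the piecewise-linear curve equals the
Mann–Whitney rank statistic (ties counted ½) *exactly*, not just
asymptotically. This identity is the module's central invariant and is
tested to 1e-12 against both the in-package rank computation and
scikit-learn's `roc_auc_score`. Interpolation between vertices is
linear everywhere (consistent with the trapezoidal area); no binormal or
kernel smoothing is offered — linear interpolation is assumption-free,
and intermediate operating points are realisable by randomising between
adjacent thresholds. Reading sensitivity at a specificity that falls on
a vertical segment returns the highest sensitivity attained there (the
curve's upper envelope). A sample whose scores are all identical is a
legitimate non-discriminative test and yields the diagonal chord
(AUROC 0.5) rather than an error.

## Isolines, success regions, compliance

Equi-PPV and equi-NPV lines are exact algebraic rearrangements of the
Bayes formulas; their correctness criterion — the side of the line a
point falls on must agree with the sign of the directly computed
predictive value minus the cutoff, everywhere — is enforced on dense
grids in the tests. The success region is the intersection of closed
half-planes (PPV ≥ PPV_c, NPV ≥ NPV_c, Sn ≥ sn_min, Sp ≥ sp_min, as
supplied) with the unit square, computed by Sutherland–Hodgman clipping
of the square; curve/region intersection is computed analytically
segment by segment (each half-plane restricts the segment parameter to
an interval), so crossing points are exact, and verdicts are invariant
under refining the curve with collinear points.

Boundary conventions:

- Inequalities are closed: a curve touching the region boundary
  complies (matching the "PPV ≥ cutoff" reading of the criteria).
- One deliberate exception: the equi-PPV line passes through (0,0) and
  the equi-NPV line through (1,1), but PPV is undefined at (0,0) (no
  test-positives) and NPV at (1,1) (no test-negatives). A curve whose
  only contact with the region is that single degenerate corner is
  judged non-compliant; otherwise the chance diagonal would "meet" any
  PPV criterion by touching the origin.
- Compliance defaults to the interpolated curve; `mode="vertices"`
  restricts the check to empirical operating points for users who do
  not accept randomised thresholds.
- A PPV cutoff at or below p (or NPV cutoff at or below 1−p) is met by
  a useless test; a warning is logged rather than an error raised.
- Eq.-(5)-style infeasible specificities (Sp < 0 required) are reported
  as-is, not clamped: some criteria are unattainable at any specificity
  and hiding that would defeat the purpose.
- For valid cutoffs (< 1) the region always contains the perfect corner
  (Sp = 1, Sn = 1), so it is never strictly empty; "unattainable"
  criteria manifest as a vanishingly small region instead. The region
  type nevertheless tolerates an empty polygon.

When both PPV and NPV cutoffs are supplied the region is their
intersection, and each criterion is additionally judged alone,
supporting split rule-in/rule-out development.

## Threshold selection

Constrained selection enumerates the empirical operating points and,
among compliant ones, maximises the complementary detection statistic:
sensitivity for rule-in, specificity for rule-out (tie-break: the other
statistic). Rationale: at equal compliance, detecting more future cases
(or clearing more non-cases) is strictly better; a `objective="youden"`
override is available since no preference is canonical. Infeasibility
is a result, not an error: the report flags it and describes the
empirical point with the smallest total constraint violation. The
classical comparators (Youden index, closest-to-(0,1), fixed
specificity) break ties towards the smallest threshold, i.e. the more
sensitive operating point.

Joint rule-in/rule-out accounting classifies each subject by the two
independent tests (flagged high-risk iff rule-in score ≥ its threshold;
cleared low-risk iff rule-out score < its threshold) into high-risk,
low-risk, conflict (flagged *and* cleared) and unclassified (neither)
groups. Population fractions are prevalence-reweighted from the
per-label-stratum rates; the raw sample fractions are reported
alongside. The four fractions sum to 1 exactly.

## Bootstrap uncertainty

Resampling is stratified (cases and controls separately, sizes
preserved) because the design fixes group sizes. Bands are pointwise
percentile intervals of sensitivity on a specificity grid (defaults:
B = 2000, level 0.95, 101 grid points; all three configurable, seed
mandatory in the CLI). Percentile rather than BCa intervals are the
simplest defensible default for a band with no canonical definition.
The three-valued verdict uses the band edges — "compliant" if the lower
edge's polyline enters the success region, "potentially compliant" if
only the point estimate or upper edge does — and separately reports the
fraction of replicate curves individually meeting the criteria, which
is computed on the full replicate curves and is therefore independent
of the grid density. Pointwise percentile bands at n of order 100 per
group are known to be slightly liberal/conservative depending on the
grid point; the coverage test brackets 90–99% rather than pinning 95%.

## Synthetic generator

The generator draws scores from Gaussian mixtures: standard-normal
controls by default, and an optional far-shifted component (5 control
SDs, essentially perfectly separated) in either class. This is the
simplest family producing the three study shapes: symmetric
(equal-variance binormal), rule-in-favourable (a well-discriminated
case fraction, steep-early ROC) and rule-out-favourable (a
well-discriminated control fraction, late-rising ROC). Population
AUROC has the closed form Σᵢⱼ wᵢvⱼ Φ((μᵢ−νⱼ)/√(σᵢ²+τⱼ²)), used as the
sampler's analytic oracle; mixture weights for a target AUROC are
solved by bisection (tolerance 1e-4 on the analytic value, achievable
range reported on infeasible targets). `equal_auc_trio` derives one
child seed per member from a single seed; no global random state is
used anywhere.

The generator emulates unimodal-to-bimodal score distributions with
label-conditional independence and exchangeable subjects. It does not
emulate calibration drift, covariate-driven case-mix shifts, repeated
measures, or verification bias — so passing tests demonstrate the
geometry and the estimators' internal consistency, not robustness of
any real biomarker panel.

A note on a boundary coincidence: the equal-variance binormal curve
with AUROC exactly 0.75 touches the success region of {PPV ≥ 0.133,
Sn ≥ 0.50, p = 0.05} with a PPV margin of ~0.001 at Sn = 0.5, so its
empirical compliance verdict at that exact criteria set is effectively
a coin flip at realistic n. The mixture-shaped members sit far from
their respective boundaries and their verdicts are stable.

## Problem sizes and numerical conventions

Default problem sizes in the test suite: 10⁴ subjects per group for
AUROC-level simulations, 10⁵ for cohort-scale Bayes-consistency checks,
500 simulated datasets × 300 bootstrap replicates for band coverage —
sizes at which Monte-Carlo error (checks use 3 standard errors) is well
below the effects asserted. Geometry tolerances are 1e-12 (exact
identities) and 1e-9 (region membership after clipping). Reported
values are rounded half-to-even to 3 decimals in human-readable output
only; machine-readable JSON keeps full precision next to a rounded
`display` block, with a `schema_version` field.

## Known limitations

- No covariate adjustment, partial AUC, or parametric ROC estimation.
- No confidence intervals for single 2×2-table predictive values.
- Simultaneous (joint) confidence bands are out of scope; the pointwise
  band can understate curve-wise uncertainty.
- Isoline-based criteria assume the evaluation and application settings
  share a case mix; a change of clinical setting invalidates the
  transported (Sn, Sp) and hence the geometry.
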