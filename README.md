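# rocpv — prevalence-aware ROC analysis for prognostic tests

`rocpv` is for biostatisticians and test developers who evaluate
prognostic (or diagnostic) risk scores with case-control data and need
to know whether a test is *clinically* useful, not just discriminative.
The AUROC ignores disease prevalence, but clinical decisions hinge on
prevalence-dependent predictive values: in a low-prevalence setting a
test with respectable sensitivity and specificity can still have a
uselessly low PPV.

The core idea is that a fixed predictive-value target traces a straight
line in ROC space (x = 1 − Sp, y = Sn). With prevalence *p* and cutoffs
PPV_c / NPV_c:

```
PPV = Sn·p / (Sn·p + (1−Sp)(1−p))            NPV = Sp(1−p) / ((1−Sn)p + Sp(1−p))

equi-PPV line:  Sn = (1−Sp) · ((1−p)/p) · PPV_c/(1−PPV_c)      (through (0,0))
equi-NPV line:  Sn = 1 − Sp · ((1−p)/p) · (1−NPV_c)/NPV_c      (through (1,1))
```

Points above an isoline exceed the cutoff. Together with minimum-Sn/Sp
requirements the isolines partition ROC space into clinical-relevance
quadrants; a test complies with a rule-in (PPV) or rule-out (NPV)
specification iff its ROC curve enters the success region. `rocpv`
builds empirical ROC curves, lays these criteria over them, tests
compliance (optionally with stratified-bootstrap confidence bands),
selects thresholds under predictive-value constraints, accounts for the
conflict group of paired rule-in/rule-out tests, and generates synthetic
equal-AUROC score sets with deliberately different ROC shapes.

## Worked example

A pre-eclampsia-style screening question: prevalence 5%, rule-in
criterion PPV ≥ 0.133 (post-test risk 1 in 7.5) with Sn ≥ 0.50.
Simulate a test whose AUROC is only 0.75 but whose cases contain a
well-discriminated fraction, then judge it:

```
$ rocpv simulate --shape rule-in --auc 0.75 --n-cases 500 --n-controls 500 \
      --seed 1 -o scores.csv
$ rocpv report scores.csv --prevalence 0.05 --ppv 0.133 --sn-min 0.5 \
      --boot 500 --seed 7 -o out
$ cat out/summary.txt
rocpv report
input: scores.csv
n = 1000 (500 cases / 500 controls; sample case fraction 0.500 — not the prevalence)
prevalence (user-supplied): 0.05
AUROC = 0.755
criteria: PPV>=0.133 NPV>=None Sn>=0.5 Sp>=None
meets criteria: True
best PPV along curve: 1.000; best NPV: 0.977
bootstrap verdict: compliant (replicate fraction 1.000)
```

The ROC curve of this modest-AUROC test crosses the equi-PPV line
(slope ((1−0.05)/0.05)·(0.133/0.867) ≈ 2.915) above Sn = 0.5, so it
meets the rule-in specification — "compliant" means even the lower 95%
bootstrap band edge enters the success region, and every one of the 500
replicate curves did too. A symmetric binormal test with the *same*
AUROC sits near this criterion's boundary, and an equally discriminative
test whose controls (rather than cases) are well separated fails it
outright: equal AUROC does not mean equal clinical utility.

From Python, the same machinery answers design questions directly — for
instance, what the common requirement "LR+ > 10 and LR− < 0.2" implies:

```python
>>> import rocpv as rp
>>> pt = rp.lr_to_min_operating_point(10, 0.2)
>>> print(f"Sn={pt.sn:.4f} Sp={pt.sp:.4f} minAUROC={rp.min_auroc_through_point(pt):.4f}")
Sn=0.8163 Sp=0.9184 minAUROC=0.8673
```

i.e. a minimum sensitivity of 0.82 with associated specificity 0.92, or
an AUROC of at least 0.87 — demanding numbers for any screening test.

Other subcommands: `rocpv roc` (empirical curve as CSV), `rocpv
isolines` (isoline segments + region vertices, directly plottable over a
ROC CSV), `rocpv comply` (verdict JSON, optional band CSV), `rocpv
select` (rule-in / rule-out / youden / corner / fixed-sp thresholds).

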