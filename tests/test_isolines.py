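"""Isoline geometry, success regions and ROC compliance."""

import numpy as np
import pytest

import rocpv as rp
from rocpv.errors import InvalidPointError


class TestSpecificityForPpv:
    def test_hand_value(self):
        assert rp.specificity_for_ppv(0.5, 0.5, 0.05) == pytest.approx(0.97368, abs=1e-4)

    def test_origin_limit(self):
        assert rp.specificity_for_ppv(0.0, 0.5, 0.05) == 1.0

    def test_even_prior(self):
        assert rp.specificity_for_ppv(1.0, 0.5, 0.5) == pytest.approx(0.0)

    def test_infeasible_reported_negative_not_clamped(self):
        # a demanding PPV at high prevalence-weighted sensitivity can need Sp < 0
        sp = rp.specificity_for_ppv(1.0, 0.05, 0.5)
        assert sp < 0


class TestIsolines:
    def test_equi_ppv_slope_and_clip(self):
        line = rp.equi_ppv_line(0.5, 0.05)
        assert line.slope == pytest.approx(19.0)
        assert line.start == (0.0, 0.0)
        assert line.end[0] == pytest.approx(1 / 19)
        assert line.end[1] == pytest.approx(1.0)

    def test_equi_ppv_at_chance(self):
        line = rp.equi_ppv_line(0.5, 0.5)
        assert line.slope == pytest.approx(1.0)  # the diagonal

    def test_rule_in_line_mid_prevalence(self):
        line = rp.equi_ppv_line(0.133, 0.05)
        assert line.slope == pytest.approx(2.915, abs=5e-4)

    def test_equi_npv_geometry(self):
        line = rp.equi_npv_line(0.988, 0.05)
        assert line.slope == pytest.approx(0.2308, abs=5e-4)
        assert line.y_at(0.0) == pytest.approx(0.769, abs=5e-4)
        assert line.y_at(1.0) == pytest.approx(1.0)

    def test_equi_npv_at_chance_is_diagonal(self):
        line = rp.equi_npv_line(0.95, 0.05)
        assert line.slope == pytest.approx(1.0)
        assert line.intercept == pytest.approx(0.0)

    def test_equi_npv_limit_horizontal(self):
        line = rp.equi_npv_line(1 - 1e-9, 0.05)
        assert line.slope == pytest.approx(0.0, abs=1e-6)

    def test_useless_cutoff_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="rocpv.isolines"):
            rp.equi_ppv_line(0.04, 0.05)
        assert "useless" in caplog.text

    @pytest.mark.parametrize("kind", ["ppv", "npv"])
    def test_side_of_line_matches_bayes_sign(self, kind):
        """Core oracle: for a grid of (sn, sp), being above/below the
        isoline agrees everywhere with the sign of the Bayes-computed
        predictive value minus the cutoff."""
        cutoff = 0.3 if kind == "ppv" else 0.97
        for p in (0.03, 0.05, 0.07, 0.2):
            line = (rp.equi_ppv_line if kind == "ppv" else rp.equi_npv_line)(cutoff, p)
            sn, sp = np.meshgrid(np.linspace(0.01, 0.99, 60), np.linspace(0.01, 0.99, 60))
            value = (rp.ppv if kind == "ppv" else rp.npv)(sn, sp, p)
            side = line.side(1.0 - sp, sn)
            diff = value - cutoff
            off_line = np.abs(sn - line.y_at(1.0 - sp)) > 1e-9
            assert np.all(np.sign(diff[off_line]) == side[off_line])
            # points constructed exactly on the line give the cutoff itself
            xs = np.linspace(max(0.01, line.start[0]), min(0.6, line.end[0]), 20)
            ys = line.y_at(xs)
            keep = (ys > 1e-6) & (ys < 1 - 1e-6)
            on_line = (rp.ppv if kind == "ppv" else rp.npv)(ys[keep], 1 - xs[keep], p)
            np.testing.assert_allclose(on_line, cutoff, atol=1e-12)

    def test_equi_ppv_slope_decreases_with_prevalence(self):
        slopes = [rp.equi_ppv_line(0.5, p).slope for p in (0.05, 0.1, 0.2)]
        assert slopes[0] > slopes[1] > slopes[2]


class TestSuccessRegion:
    def test_quadrant_vertex(self):
        region = rp.success_region(rp.PredictiveCriteria(0.05, ppv_c=0.5, sn_min=0.5))
        verts = np.array(region.vertices)
        expected = (0.5 / 19, 0.5)
        assert any(np.allclose(v, expected, atol=1e-12) for v in verts)

    def test_chance_cutoff_gives_upper_triangle(self):
        region = rp.success_region(rp.PredictiveCriteria(0.5, ppv_c=0.5))
        assert set(map(tuple, np.round(region.vertices, 12))) == {
            (0.0, 0.0), (1.0, 1.0), (0.0, 1.0)
        }

    def test_demanding_joint_criteria_nonempty_wedge(self):
        region = rp.success_region(
            rp.PredictiveCriteria(0.05, ppv_c=0.133, npv_c=0.988)
        )
        assert not region.is_empty
        verts = np.array(region.vertices)
        # wedge near the top-left corner of ROC space
        assert verts[:, 0].max() < 0.45 and verts[:, 1].min() > 0.55
        assert region.contains(0.0, 1.0)

    def test_perfect_corner_always_feasible_but_region_can_be_tiny(self):
        # the perfect test (sp=1, sn=1) meets any cutoffs below 1, so the
        # region is never empty -- but it can shrink to a sliver whose
        # demands no realistic test meets
        criteria = rp.PredictiveCriteria(0.001, ppv_c=0.99, sn_min=0.9)
        region = rp.success_region(criteria)
        assert region.contains(0.0, 1.0)
        verts = np.array(region.vertices)
        area = 0.5 * abs(
            np.dot(verts[:, 0], np.roll(verts[:, 1], -1))
            - np.dot(verts[:, 1], np.roll(verts[:, 0], -1))
        )
        assert area < 1e-3

    def test_region_vertices_satisfy_all_constraints(self):
        criteria = rp.PredictiveCriteria(0.05, ppv_c=0.2, npv_c=0.98, sn_min=0.3, sp_min=0.2)
        region = rp.success_region(criteria)
        for x, y in region.vertices:
            assert region.contains(x, y)

    def test_criteria_require_a_cutoff(self):
        with pytest.raises(ValueError):
            rp.PredictiveCriteria(0.05, sn_min=0.5)


class TestCompliance:
    def test_perfect_curve_meets(self, perfect_data):
        curve = rp.empirical_roc(perfect_data)
        criteria = rp.PredictiveCriteria(0.05, ppv_c=0.9, npv_c=0.99, sn_min=0.9, sp_min=0.9)
        assert rp.roc_meets_criteria(curve, criteria).meets

    def test_diagonal_fails_above_chance_ppv(self):
        curve = rp.RocCurve.from_fpr_tpr([0, 1], [0, 1])
        report = rp.roc_meets_criteria(curve, rp.PredictiveCriteria(0.05, ppv_c=0.133))
        assert not report.meets
        assert report.best_ppv == pytest.approx(0.05, abs=1e-9)

    def test_steep_early_curve_meets_rule_in(self):
        curve = rp.RocCurve.from_fpr_tpr([0, 0.02, 1], [0, 0.55, 1])
        criteria = rp.PredictiveCriteria(0.05, ppv_c=0.133, sn_min=0.5)
        report = rp.roc_meets_criteria(curve, criteria)
        assert report.meets
        # vertex (0.02, 0.55) itself complies: PPV ~ 0.591
        assert rp.ppv(0.55, 0.98, 0.05) == pytest.approx(0.591, abs=5e-4)
        assert report.best_ppv >= 0.591

    def test_crossings_lie_on_region_boundary(self):
        curve = rp.RocCurve.from_fpr_tpr([0, 0.02, 1], [0, 0.55, 1])
        criteria = rp.PredictiveCriteria(0.05, ppv_c=0.133, sn_min=0.5)
        report = rp.roc_meets_criteria(curve, criteria)
        assert report.crossings
        for x, y in report.crossings:
            on_some_boundary = any(
                abs(con.value(x, y)) < 1e-9 for con in report.region.constraints
            )
            assert on_some_boundary and report.region.contains(x, y)

    def test_interpolated_vs_vertex_mode(self):
        # one curve segment passes through the wedge {sn>=0.5, sp>=0.8}
        # even though no empirical vertex lies inside it
        curve = rp.RocCurve.from_fpr_tpr(
            [0, 0.15, 0.5, 1], [0, 0.45, 0.95, 1]
        )
        criteria = rp.PredictiveCriteria(0.05, ppv_c=0.052, sn_min=0.5, sp_min=0.8)
        assert rp.roc_meets_criteria(curve, criteria, mode="interpolated").meets
        assert not rp.roc_meets_criteria(curve, criteria, mode="vertices").meets

    def test_refinement_invariance(self, rng):
        """Adding collinear interpolated points does not change the verdict."""
        data = rp.LabeledScores(rng.normal(size=200) + np.r_[np.ones(100), np.zeros(100)],
                                np.r_[np.ones(100), np.zeros(100)])
        curve = rp.empirical_roc(data)
        # refine each segment with midpoints
        fpr = np.repeat(curve.fpr, 2)[1:]
        tpr = np.repeat(curve.tpr, 2)[1:]
        fpr[1::2] = (curve.fpr[:-1] + curve.fpr[1:]) / 2
        tpr[1::2] = (curve.tpr[:-1] + curve.tpr[1:]) / 2
        refined = rp.RocCurve.from_fpr_tpr(fpr, tpr)
        for criteria in (
            rp.PredictiveCriteria(0.05, ppv_c=0.133, sn_min=0.5),
            rp.PredictiveCriteria(0.05, npv_c=0.988, sp_min=0.5),
            rp.PredictiveCriteria(0.05, ppv_c=0.6),
        ):
            assert (
                rp.roc_meets_criteria(curve, criteria).meets
                == rp.roc_meets_criteria(refined, criteria).meets
            )

    def test_joint_criteria_reports_split_verdicts(self, perfect_data):
        curve = rp.empirical_roc(perfect_data)
        criteria = rp.PredictiveCriteria(0.05, ppv_c=0.133, npv_c=0.988)
        report = rp.roc_meets_criteria(curve, criteria)
        assert report.meets_rule_in and report.meets_rule_out


class TestLikelihoodRatioRequirements:
    def test_joint_lr_operating_point(self):
        pt = rp.lr_to_min_operating_point(10, 0.2)
        assert round(pt.sn, 2) == 0.82
        assert round(pt.sp, 2) == 0.92
        assert pt.sn == pytest.approx(0.8163, abs=5e-5)
        assert pt.sp == pytest.approx(0.9184, abs=5e-5)

    def test_hand_algebra_case(self):
        pt = rp.lr_to_min_operating_point(2, 0.5)
        assert pt.sn == pytest.approx(2 / 3)
        assert pt.sp == pytest.approx(2 / 3)

    def test_near_chance_limit(self):
        pt = rp.lr_to_min_operating_point(1 + 1e-6, 1 - 1e-6)
        assert pt.sn == pytest.approx(0.5, abs=1e-3)
        assert pt.sp == pytest.approx(0.5, abs=1e-3)

    def test_min_auroc_values(self):
        pt = rp.lr_to_min_operating_point(10, 0.2)
        assert round(rp.min_auroc_through_point(pt), 2) == 0.87
        assert rp.min_auroc_through_point(rp.OperatingPoint(0, 1, 1)) == 1.0
        assert rp.min_auroc_through_point(rp.OperatingPoint(0, 0.5, 0.5)) == 0.5

    def test_below_diagonal_rejected(self):
        with pytest.raises(InvalidPointError):
            rp.min_auroc_through_point(rp.OperatingPoint(0, 0.3, 0.3))

    def test_min_auroc_is_a_lower_bound_over_concave_curves(self, rng):
        """Brute-force oracle: random concave piecewise-linear curves
        through the point never have smaller area than (sn+sp)/2."""
        pt = rp.lr_to_min_operating_point(10, 0.2)
        px, py = 1 - pt.sp, pt.sn
        bound = rp.min_auroc_through_point(pt)
        found = 0
        for _ in range(500):
            x1 = rng.uniform(0, px)
            # concavity: slope(0->v1) >= slope(v1->pt) and y1 <= chord-free
            y1 = rng.uniform(py * x1 / px, min(1.0, py))
            x2 = rng.uniform(px, 1)
            y2 = rng.uniform(py, 1)
            xs = np.array([0, x1, px, x2, 1.0])
            ys = np.array([0, y1, py, y2, 1.0])
            slopes = np.diff(ys) / np.diff(xs)
            if np.any(np.diff(slopes) > 1e-12):
                continue  # not concave; skip
            found += 1
            assert rp.auroc_trapezoid(list(zip(xs, ys))) >= bound - 1e-12
        assert found > 50
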