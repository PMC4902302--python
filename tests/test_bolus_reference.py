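"""Bolus reference, enhancement normalization, cohort calibration, CT line."""

import numpy as np
import pytest

from killfrac.bolus_reference import (
    CohortRecord,
    CtBvfLine,
    bolus_fkill,
    calibrate_cohort,
    enhancement_curve,
    fit_ct_bvf,
    predict_fkill_from_ct,
)
from killfrac.kill_dynamics import run_kill_curve
from killfrac.model_core import DimensionlessParams, ParameterError
from killfrac.synthetic_cohort import CohortGenSpec, gen_cohort

TRUTH_RB, TRUTH_L = 15.83, 155.06


class TestBolusFkill:
    def test_is_model_kill_at_one_cycle_by_definition(self):
        dp = DimensionlessParams(rb_over_L=0.102, BVF=0.01)
        curve = run_kill_curve(dp, t_end=1.0, dt=5e-3, n_nodes=301)
        assert bolus_fkill(dp, dt=5e-3, n_nodes=301) == curve.f_kill[-1]

    def test_high_bvf_limit_is_wall_kill_level(self):
        """As BVF -> 1 the influenced annulus collapses onto the vessel wall
        where sigma' = 1; there the kill dynamics reduce to
        dphi/dt = -phi * int(phi), whose solution is phi(t) = sech^2(t/sqrt(2)),
        so one cycle kills 1 - sech^2(1/sqrt(2)) ~ 0.371 of cells."""
        f = bolus_fkill(DimensionlessParams(rb_over_L=0.1, BVF=0.95), dt=1e-3, n_nodes=301)
        assert f == pytest.approx(1.0 - np.cosh(1.0 / np.sqrt(2.0)) ** -2, abs=5e-3)

    def test_strictly_increasing_in_bvf(self):
        vals = [
            bolus_fkill(DimensionlessParams(0.1, b), dt=5e-3, n_nodes=301)
            for b in (0.005, 0.01, 0.05)
        ]
        assert vals[0] < vals[1] < vals[2]


class TestEnhancement:
    def test_self_normalization_at_bolus_time(self, curve_intermediate):
        bolus = curve_intermediate.at(1.0)
        ratio = enhancement_curve(curve_intermediate, bolus)
        idx = int(np.argmin(np.abs(curve_intermediate.t_prime - 1.0)))
        assert ratio[idx] == pytest.approx(1.0, rel=1e-12)

    def test_ratio_at_least_one_beyond_bolus_time(self, curve_intermediate):
        bolus = curve_intermediate.at(1.0)
        ratio = enhancement_curve(curve_intermediate, bolus)
        mask = curve_intermediate.t_prime >= 1.0
        assert np.all(ratio[mask] >= 1.0 - 1e-12)

    def test_high_bvf_enhancement_is_smaller_at_late_times(
        self, curve_intermediate, curve_high_bvf
    ):
        """Highly vascularized tumors are mostly killed within 1-2 cycles, so
        sustained release gains less over bolus than at reference BVF."""
        r_mid = enhancement_curve(curve_intermediate, curve_intermediate.at(1.0))
        r_high = enhancement_curve(curve_high_bvf, curve_high_bvf.at(1.0))
        idx = int(np.argmin(np.abs(curve_intermediate.t_prime - 6.0)))
        assert r_high[idx] < r_mid[idx]

    def test_zero_bolus_rejected(self, curve_intermediate):
        with pytest.raises(ParameterError):
            enhancement_curve(curve_intermediate, 0.0)


class TestBolusTable:
    def test_interpolation_accuracy_against_direct_solves(self, bolus_table, rng):
        for _ in range(6):
            a = 10 ** rng.uniform(np.log10(0.03), np.log10(0.5))
            b = 10 ** rng.uniform(np.log10(1e-3), np.log10(0.2))
            direct = bolus_table.direct(b, a * 100.0, 100.0)
            assert abs(bolus_table.evaluate(a, b) - direct) < 1e-4

    def test_out_of_range_rejected(self, bolus_table):
        with pytest.raises(ParameterError):
            bolus_table.evaluate(5.0, 0.01)


class TestCalibration:
    def test_zero_noise_exact_recovery(self, bolus_table):
        records = gen_cohort(
            CohortGenSpec(noise_sd_fkill=0.0, ct_cv=0.0, seed=11), model=bolus_table
        )
        fit = calibrate_cohort(records, model=bolus_table, r_b=TRUTH_RB)
        assert fit.L == pytest.approx(TRUTH_L, rel=1e-6)
        assert fit.r_b == TRUTH_RB
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_record_order_invariance(self, bolus_table, rng):
        records = gen_cohort(CohortGenSpec(noise_sd_fkill=0.05, seed=12), model=bolus_table)
        fit1 = calibrate_cohort(records, model=bolus_table, r_b=TRUTH_RB)
        shuffled = list(records)
        rng.shuffle(shuffled)
        fit2 = calibrate_cohort(shuffled, model=bolus_table, r_b=TRUTH_RB)
        assert fit1.L == pytest.approx(fit2.L, rel=1e-12)
        assert fit1.r_squared == pytest.approx(fit2.r_squared, rel=1e-12)

    def test_under_determined_cohort_rejected(self, bolus_table):
        records = gen_cohort(CohortGenSpec(seed=1), model=bolus_table)[:2]
        with pytest.raises(ParameterError, match=">= 3"):
            calibrate_cohort(records, model=bolus_table)

    def test_constant_bvf_rejected(self):
        records = [
            CohortRecord(patient_id=f"P{i}", bvf=0.01, f_kill=0.3) for i in range(5)
        ]
        with pytest.raises(ParameterError, match="identical"):
            calibrate_cohort(records)

    def test_weighted_requires_spreads(self, bolus_table):
        records = [
            CohortRecord(patient_id=f"P{i}", bvf=b, f_kill=0.3, f_kill_sd=0.0)
            for i, b in enumerate((0.005, 0.01, 0.05))
        ]
        with pytest.raises(ParameterError, match="f_kill_sd"):
            calibrate_cohort(records, model=bolus_table, weighted=True)

    def test_reports_finite_uncertainty_under_noise(self, bolus_table):
        records = gen_cohort(CohortGenSpec(noise_sd_fkill=0.05, seed=13), model=bolus_table)
        fit = calibrate_cohort(records, model=bolus_table, r_b=TRUTH_RB)
        assert fit.se_L > 0
        assert 0 <= fit.p_L <= 1
        assert fit.r_b_fixed


class TestCtBvfLine:
    def test_exact_line_recovered(self):
        slope, intercept = 8e-4, 2e-3
        records = [
            CohortRecord(patient_id=f"P{i}", bvf=slope * hu + intercept, f_kill=0.3, hu=hu)
            for i, hu in enumerate((10.0, 30.0, 60.0, 90.0))
        ]
        line = fit_ct_bvf(records)
        assert line.slope == pytest.approx(slope, rel=1e-12)
        assert line.intercept == pytest.approx(intercept, rel=1e-9)
        assert line.r_squared == pytest.approx(1.0)

    def test_constant_hu_rejected(self):
        records = [
            CohortRecord(patient_id=f"P{i}", bvf=b, f_kill=0.3, hu=50.0)
            for i, b in enumerate((0.005, 0.01, 0.05))
        ]
        with pytest.raises(ParameterError, match="identical"):
            fit_ct_bvf(records)

    def test_too_few_hu_records_rejected(self):
        records = [CohortRecord(patient_id="P1", bvf=0.01, f_kill=0.3, hu=50.0)]
        with pytest.raises(ParameterError, match=">= 3"):
            fit_ct_bvf(records)


class TestPredictFromCt:
    def test_composition_matches_bolus_model(self, bolus_table):
        records = gen_cohort(CohortGenSpec(noise_sd_fkill=0.0, ct_cv=0.0, seed=14), model=bolus_table)
        fit = calibrate_cohort(records, model=bolus_table, r_b=TRUTH_RB)
        line = fit_ct_bvf(records)
        rec = records[0]
        hu = (rec.bvf - line.intercept) / line.slope  # HU that maps back to this BVF
        pred = predict_fkill_from_ct(hu, line, fit, model=bolus_table)
        assert pred == pytest.approx(bolus_table(rec.bvf, fit.r_b, fit.L), rel=1e-9)

    def test_end_to_end_prediction_error_at_clinical_noise(self, bolus_table):
        """CT-driven prediction against generated truth: mean relative error
        below 30% at generator noise emulating observed clinical spread."""
        records = gen_cohort(CohortGenSpec(noise_sd_fkill=0.05, ct_cv=0.25, seed=15), model=bolus_table)
        fit = calibrate_cohort(records, model=bolus_table, r_b=TRUTH_RB)
        line = fit_ct_bvf(records)
        rel_errors = []
        for rec in records:
            truth = bolus_table(rec.bvf, TRUTH_RB, TRUTH_L)
            try:
                pred = predict_fkill_from_ct(rec.hu, line, fit, model=bolus_table)
            except ParameterError:
                continue
            rel_errors.append(abs(pred - truth) / truth)
        assert len(rel_errors) >= 15
        assert np.mean(rel_errors) < 0.30

    def test_out_of_range_bvf_names_offending_hu(self, bolus_table):
        line = CtBvfLine(slope=1e-3, intercept=0.0, r_squared=1.0, p_value_slope=0.0)
        records = gen_cohort(CohortGenSpec(noise_sd_fkill=0.0, ct_cv=0.0, seed=16), model=bolus_table)
        fit = calibrate_cohort(records, model=bolus_table, r_b=TRUTH_RB)
        with pytest.raises(ParameterError, match="HU=-5"):
            predict_fkill_from_ct(-5.0, line, fit, model=bolus_table)
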