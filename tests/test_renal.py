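"""Kidney-function engine: eGFR, baselines, KDIGO staging, CKD bands, recovery."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipaki.renal import (
    BaselineProvenance,
    BaselineResult,
    CKDStageLabel,
    NotAssessableError,
    TriggerRule,
    assess_episode,
    ckd_stage,
    ckd_stage_from_egfr,
    classify_recovery,
    compute_egfr_mdrd,
    establish_baseline,
    estimate_baseline_scr,
    stage_single,
)

from conftest import make_series


class TestMDRD:
    def test_hand_evaluated_reference_values(self):
        # 175 x (1.0)^-1.154 x 60^-0.203 = 76.2 for a non-black man at SCr 88.4
        assert compute_egfr_mdrd(88.4, 60, "M") == pytest.approx(76.2, abs=0.1)
        assert compute_egfr_mdrd(88.4, 60, "F") == pytest.approx(76.2 * 0.742, abs=0.1)
        assert compute_egfr_mdrd(88.4, 60, "M", "black") == pytest.approx(76.2 * 1.212, abs=0.1)

    def test_unknown_ethnicity_is_non_black(self):
        assert compute_egfr_mdrd(100, 80, "F", "unknown") == compute_egfr_mdrd(100, 80, "F")

    def test_higher_creatinine_means_lower_egfr(self):
        assert compute_egfr_mdrd(200, 70, "M") < compute_egfr_mdrd(100, 70, "M")

    @pytest.mark.parametrize("scr", [0, -5])
    def test_non_positive_creatinine_rejected(self, scr):
        with pytest.raises(ValueError):
            compute_egfr_mdrd(scr, 70, "M")

    def test_backward_estimate_reference_value(self):
        assert estimate_baseline_scr(60, "M") == pytest.approx(89.7, abs=0.1)

    @given(
        age=st.floats(18, 105),
        female=st.booleans(),
        black=st.booleans(),
    )
    @settings(deadline=None, max_examples=50)
    def test_backward_estimate_inverts_forward_equation(self, age, female, black):
        sex = "F" if female else "M"
        eth = "black" if black else "non_black"
        scr = estimate_baseline_scr(age, sex, eth, assumed_egfr=75)
        assert compute_egfr_mdrd(scr, age, sex, eth) == pytest.approx(75, abs=1e-9)

    def test_female_estimate_below_male(self):
        assert estimate_baseline_scr(70, "F") < estimate_baseline_scr(70, "M")


class TestBaseline:
    def test_mean_of_window_values(self):
        series = make_series(pre=((30, 80.0), (200, 120.0)))
        result = establish_baseline(series, 83, "F")
        assert result.value == pytest.approx(100.0)
        assert result.provenance is BaselineProvenance.MEASURED_MEAN
        assert result.n_values_used == 2

    def test_value_inside_seven_day_exclusion_ignored(self):
        series = make_series(pre=((3, 90.0),))
        result = establish_baseline(series, 83, "F")
        assert result.provenance is BaselineProvenance.ESTIMATED
        assert result.n_values_used == 0

    def test_no_values_falls_back_to_estimate(self):
        series = make_series(inpatient=((0, 100.0),))
        result = establish_baseline(series, 60, "M")
        assert result.value == pytest.approx(89.7, abs=0.1)
        assert result.provenance is BaselineProvenance.ESTIMATED


class TestStageSingle:
    @pytest.mark.parametrize(
        "scr,baseline,prior,stage,rule",
        [
            (160, 100, False, 1, TriggerRule.RATIO),
            (127, 100, False, 1, TriggerRule.ABSOLUTE_RISE),
            (124, 100, False, 0, TriggerRule.NONE),
            (210, 100, False, 2, TriggerRule.RATIO),
            (300, 100, False, 3, TriggerRule.RATIO),
            (360, 150, True, 3, TriggerRule.SCR_GE_353_6),
            (360, 150, False, 3, TriggerRule.SCR_GE_353_6),  # meets stage 1 itself
            (360, 340, False, 0, TriggerRule.NONE),  # >=353.6 without stage 1 anywhere
            (150, 100, False, 1, TriggerRule.RATIO),  # exactly 1.5x
            (200, 100, False, 2, TriggerRule.RATIO),  # band edge 2.0 is stage 2
        ],
    )
    def test_kdigo_bands(self, scr, baseline, prior, stage, rule):
        assert stage_single(scr, baseline, prior) == (stage, rule)

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(ValueError):
            stage_single(100, 0)

    @given(
        baseline=st.floats(40, 300),
        scr_lo=st.floats(40, 1000),
        scr_hi=st.floats(40, 1000),
        prior=st.booleans(),
    )
    @settings(deadline=None, max_examples=200)
    def test_stage_monotone_in_creatinine(self, baseline, scr_lo, scr_hi, prior):
        lo, hi = sorted((scr_lo, scr_hi))
        assert stage_single(lo, baseline, prior)[0] <= stage_single(hi, baseline, prior)[0]


class TestAssessEpisode:
    def test_rolling_staging_and_worst(self):
        series = make_series(inpatient=((0, 110.0), (2, 160.0), (4, 210.0)))
        baseline = BaselineResult(100.0, BaselineProvenance.MEASURED_MEAN, 2, (7, 365))
        result = assess_episode(series, baseline)
        assert [s for _, s, _ in result.per_measurement] == [0, 1, 2]
        assert result.worst_stage == 2
        assert result.admission_stage == 0

    def test_rrt_forces_stage_three(self):
        series = make_series(inpatient=((0, 100.0),))
        baseline = BaselineResult(100.0, BaselineProvenance.MEASURED_MEAN, 1, (7, 365))
        result = assess_episode(series, baseline, rrt_flag=True)
        assert result.worst_stage == 3

    def test_stage1_carry_forward_enables_absolute_stage3(self):
        # 355 alone vs baseline 340 is stage 0; after an earlier stage 1 it is 3
        series = make_series(inpatient=((0, 340 * 1.6), (2, 355.0)))
        baseline = BaselineResult(340.0, BaselineProvenance.MEASURED_MEAN, 1, (7, 365))
        result = assess_episode(series, baseline)
        assert result.per_measurement[1][1] == 3
        assert result.per_measurement[1][2] is TriggerRule.SCR_GE_353_6

    def test_no_inpatient_measurements_not_assessable(self):
        series = make_series(pre=((30, 90.0),))
        baseline = BaselineResult(90.0, BaselineProvenance.MEASURED_MEAN, 1, (7, 365))
        with pytest.raises(NotAssessableError):
            assess_episode(series, baseline)

    def test_worst_stage_order_free_without_absolute_rule(self):
        baseline = BaselineResult(100.0, BaselineProvenance.MEASURED_MEAN, 1, (7, 365))
        values = [105.0, 155.0, 220.0, 130.0]
        worsts = set()
        import itertools

        for perm in itertools.permutations(values):
            series = make_series(inpatient=tuple((d, v) for d, v in enumerate(perm)))
            worsts.add(assess_episode(series, baseline).worst_stage)
        assert worsts == {2}


class TestCKD:
    @pytest.mark.parametrize(
        "egfr,label",
        [
            (95, CKDStageLabel.G1),
            (90, CKDStageLabel.G1),
            (75, CKDStageLabel.G2),
            (50, CKDStageLabel.G3A),
            (40, CKDStageLabel.G3B),
            (20, CKDStageLabel.G4),
            (10, CKDStageLabel.G5),
        ],
    )
    def test_band_assignment(self, egfr, label):
        assert ckd_stage_from_egfr(egfr) is label

    @given(egfr=st.floats(0.1, 200))
    @settings(deadline=None, max_examples=100)
    def test_bands_partition_positive_egfr(self, egfr):
        # exactly one stage for every finite positive eGFR
        label = ckd_stage_from_egfr(egfr)
        assert label in CKDStageLabel

    def test_imputed_stage2_when_no_baseline(self):
        series = make_series(inpatient=((0, 100.0),))
        result = ckd_stage(series, 83, "F", impute_stage2=True)
        assert result.stage is CKDStageLabel.G2
        assert result.basis == "imputed_stage2"

    def test_no_values_without_imputation_raises(self):
        series = make_series(inpatient=((0, 100.0),))
        with pytest.raises(NotAssessableError):
            ckd_stage(series, 83, "F", impute_stage2=False)

    def test_post_discharge_basis(self):
        series = make_series(post=((120, 130.0), (200, 150.0)))
        result = ckd_stage(series, 83, "F", basis="post_discharge")
        assert result.egfr == pytest.approx(compute_egfr_mdrd(140.0, 83, "F"))


class TestRecovery:
    def _baseline(self, value=100.0, provenance=BaselineProvenance.MEASURED_MEAN):
        n = 1 if provenance is BaselineProvenance.MEASURED_MEAN else 0
        return BaselineResult(value, provenance, n, (7, 365))

    def test_percent_change(self):
        series = make_series(post=((120, 130.0),))
        result = classify_recovery(series, self._baseline())
        assert result.evaluable
        assert result.percent_change == pytest.approx(30.0)

    def test_unchanged_function_is_zero(self):
        series = make_series(post=((120, 100.0),))
        assert classify_recovery(series, self._baseline()).percent_change == pytest.approx(0.0)

    def test_early_values_outside_window_not_evaluable(self):
        series = make_series(post=((30, 100.0),))
        assert not classify_recovery(series, self._baseline()).evaluable

    def test_estimated_baseline_not_evaluable(self):
        series = make_series(post=((120, 100.0),))
        baseline = self._baseline(provenance=BaselineProvenance.ESTIMATED)
        result = classify_recovery(series, baseline)
        assert not result.evaluable
        assert result.percent_change is None
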