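"""Validation statistics: split, AUROC/DeLong, Hosmer-Lemeshow, Wilson/Koopman."""

import numpy as np
import pytest
from statsmodels.stats.proportion import confint_proportions_2indep

from hipaki.validation import (
    auroc_delong,
    calibration_table,
    hosmer_lemeshow,
    koopman_ci,
    stratified_split,
    threshold_metrics,
    wilson_ci,
)


def brute_force_auc(scores, labels):
    """Exhaustive case-control pair counting (ties count one half)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = 0.0
    for c in cases:
        for d in controls:
            wins += 1.0 if c > d else (0.5 if c == d else 0.0)
    return wins / (len(cases) * len(controls))


class TestStratifiedSplit:
    def test_exact_stratified_counts(self):
        ids = np.arange(300)
        outcome = np.array([1] * 100 + [0] * 200)
        split = stratified_split(ids, outcome, ratio=0.66, seed=0)
        train = set(split.training_ids)
        assert sum(1 for i in train if i < 100) == 66
        assert sum(1 for i in train if i >= 100) == 132

    def test_partition_and_determinism(self):
        rng = np.random.default_rng(3)
        ids = np.arange(517)
        outcome = rng.integers(0, 2, 517)
        a = stratified_split(ids, outcome, seed=42)
        b = stratified_split(ids, outcome, seed=42)
        assert a.training_ids == b.training_ids
        assert sorted(a.training_ids + a.testing_ids) == list(ids)

    def test_prevalence_preserved(self):
        rng = np.random.default_rng(4)
        ids = np.arange(1000)
        outcome = rng.binomial(1, 0.24, 1000)
        split = stratified_split(ids, outcome, seed=1)
        p_train = outcome[split.training_ids].mean()
        p_test = outcome[split.testing_ids].mean()
        assert abs(p_train - p_test) < 0.01

    def test_tiny_stratum_goes_to_training(self):
        ids = np.arange(10)
        outcome = np.array([1] + [0] * 9)
        split = stratified_split(ids, outcome, seed=0)
        assert 0 in split.training_ids


class TestAUROCDeLong:
    def test_perfect_separation(self):
        auc, _ = auroc_delong([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc == 1.0

    def test_hand_counted_example(self):
        auc, _ = auroc_delong([1, 3, 2, 4], [0, 0, 1, 1])
        assert auc == 0.75

    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_matches_brute_force_pair_counting(self, n):
        rng = np.random.default_rng(n)
        labels = rng.integers(0, 2, n)
        labels[0], labels[1] = 0, 1  # both classes present
        scores = np.round(rng.normal(labels, 1.2), 1)  # ties likely
        auc, (lo, hi) = auroc_delong(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert 0.0 <= lo <= auc <= hi <= 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        scores = rng.normal(labels, 1.0)
        a1, _ = auroc_delong(scores, labels)
        a2, _ = auroc_delong(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc_delong([1, 2, 3], [1, 1, 1])

    def test_ci_coverage_binormal(self):
        # true AUC for N(0,1) vs N(mu,1) scores is Phi(mu/sqrt(2))
        from scipy.stats import norm

        mu = 1.0
        true_auc = norm.cdf(mu / np.sqrt(2))
        rng = np.random.default_rng(123)
        covered = 0
        reps = 300
        for _ in range(reps):
            controls = rng.normal(0, 1, 60)
            cases = rng.normal(mu, 1, 40)
            scores = np.concatenate([controls, cases])
            labels = np.array([0] * 60 + [1] * 40)
            _, (lo, hi) = auroc_delong(scores, labels)
            covered += lo <= true_auc <= hi
        assert covered / reps == pytest.approx(0.95, abs=0.04)


class TestHosmerLemeshow:
    def test_statistic_non_negative_and_df(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.6, 500)
        y = rng.binomial(1, p)
        stat, df, pval = hosmer_lemeshow(p, y, groups=10)
        assert stat >= 0
        assert df == 8
        assert 0 <= pval <= 1

    def test_flat_predictions_merge_to_single_group(self):
        y = np.array([0, 1] * 50)
        p = np.full(100, 0.5)
        stat, df, _ = hosmer_lemeshow(p, y, groups=10)
        # all quantile boundaries coincide: one group remains, df floored at 1
        assert df == 1
        assert stat == pytest.approx(0.0, abs=1e-9)

    def test_grouping_by_integer_score(self):
        rng = np.random.default_rng(6)
        score = rng.integers(0, 9, 600)
        p = 1 / (1 + np.exp(2.264 - score / 4))
        y = rng.binomial(1, p)
        stat, df, _ = hosmer_lemeshow(p, y, group_labels=score)
        assert df == len(np.unique(score)) - 2

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.2, 1.0, 0.4] * 10, [0, 1, 0] * 10)

    def test_badly_calibrated_model_rejected(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.05, 0.4, 2000)
        y = rng.binomial(1, np.clip(p + 0.15, 0, 1))  # systematic under-prediction
        _, _, pval = hosmer_lemeshow(p, y, groups=10)
        assert pval < 0.01


class TestCalibrationTable:
    def test_rows_partition_dataset(self):
        rng = np.random.default_rng(9)
        scores = {"full": rng.integers(0, 9, 400)}
        outcomes = {"full": rng.binomial(1, 0.25, 400)}
        table = calibration_table(scores, outcomes, lambda s: s / 10, max_score=8)
        assert table["full_n"].sum() == 400
        assert len(table) == 9

    def test_empty_score_group_blank_observed(self):
        scores = {"full": np.array([0, 0, 2])}
        outcomes = {"full": np.array([0, 1, 1])}
        table = calibration_table(scores, outcomes, lambda s: s / 10, max_score=2)
        row = table[table["score"] == 1].iloc[0]
        assert row["full_n"] == 0
        assert row["full_observed"] is None or np.isnan(row["full_observed"])


class TestWilson:
    def test_closed_form_oracle(self):
        assert wilson_ci(5, 10) == pytest.approx((0.2366, 0.7634), abs=1e-3)

    def test_zero_events_lower_bound_zero(self):
        lo, hi = wilson_ci(0, 10)
        assert lo == 0.0
        assert hi > 0

    @pytest.mark.parametrize("k,n", [(1, 7), (13, 40), (99, 100)])
    def test_interval_contains_point_estimate(self, k, n):
        lo, hi = wilson_ci(k, n)
        assert lo <= k / n <= hi


class TestKoopman:
    @pytest.mark.parametrize("k1,n1,k2,n2", [(5, 10, 3, 12), (20, 50, 30, 60), (1, 20, 10, 25)])
    def test_matches_independent_score_interval(self, k1, n1, k2, n2):
        # statsmodels' score interval for a risk ratio additionally inflates
        # the variance by N/(N-1) (Miettinen-Nurminen); passing the alpha whose
        # chi2(1) critical value equals 3.8415 * N/(N-1) makes the two
        # inversions target the same equation.
        from scipy.stats import chi2

        n_total = n1 + n2
        adj_alpha = 1 - chi2.cdf(chi2.ppf(0.95, 1) * n_total / (n_total - 1), 1)
        lo, hi = koopman_ci(k1, n1, k2, n2, alpha=adj_alpha)
        ref_lo, ref_hi = confint_proportions_2indep(
            k1, n1, k2, n2, compare="ratio", method="score"
        )
        assert lo == pytest.approx(ref_lo, rel=1e-3)
        assert hi == pytest.approx(ref_hi, rel=1e-3)

    def test_bounds_sit_exactly_on_chi2_critical_value(self):
        from hipaki.validation import _koopman_stat
        from scipy.stats import chi2

        crit = chi2.ppf(0.95, 1)
        for k1, n1, k2, n2 in [(5, 10, 3, 12), (20, 50, 30, 60), (1, 20, 10, 25)]:
            lo, hi = koopman_ci(k1, n1, k2, n2)
            assert _koopman_stat(lo, k1, n1, k2, n2) == pytest.approx(crit, abs=1e-6)
            assert _koopman_stat(hi, k1, n1, k2, n2) == pytest.approx(crit, abs=1e-6)

    def test_zero_denominator_gives_open_upper_bound(self):
        lo, hi = koopman_ci(5, 10, 0, 10)
        assert np.isinf(hi)
        assert lo > 0

    def test_zero_numerator_lower_bound_zero(self):
        lo, hi = koopman_ci(0, 10, 5, 10)
        assert lo == 0.0
        assert np.isfinite(hi)

    def test_interval_contains_ratio(self):
        lo, hi = koopman_ci(8, 30, 12, 40)
        assert lo < (8 / 30) / (12 / 40) < hi


class TestThresholdMetrics:
    def test_counts_and_wilson_intervals(self):
        scores = np.array([0, 1, 2, 5, 6, 7, 8, 3])
        labels = np.array([0, 0, 0, 1, 1, 0, 1, 0])
        out = threshold_metrics(scores, labels, cutoff=5)
        assert (out["tp"], out["fp"], out["fn"], out["tn"]) == (3, 1, 0, 4)
        lo, hi = out["sensitivity_ci"]
        assert lo <= out["sensitivity"] <= hi
        assert out["lr_pos"] == pytest.approx((3 / 3) / (1 / 5))
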