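"""EGG ratio, reference interval, classification, and paired clearance test."""

import numpy as np
import pytest
import scipy.stats

from eggdosage.classifier import (
    NEGATIVE,
    POSITIVE,
    PerformanceReport,
    ReferenceInterval,
    classify,
    clearance_test,
    egg_ratio,
    evaluate,
    reference_interval,
)
from eggdosage.digital import UnanalyzableSampleError
from eggdosage.stats import wilcoxon_signed_rank
from eggdosage.synthetic import EUPLOID, TRISOMY18


class TestEggRatio:
    def test_ratio_arithmetic(self):
        assert egg_ratio(30, 20).ratio == pytest.approx(1.5)
        assert egg_ratio(0, 20).ratio == 0.0

    def test_zero_reference_is_unanalyzable_never_coerced(self):
        with pytest.raises(UnanalyzableSampleError):
            egg_ratio(30, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            egg_ratio(-1, 5)


class TestReferenceInterval:
    def test_zero_variance_collapses_to_point(self):
        interval = reference_interval([1.5, 1.5, 1.5])
        assert interval.lower == interval.upper == 1.5

    def test_hand_computed_two_point_interval(self):
        interval = reference_interval([1.0, 2.0])
        assert interval.mean == pytest.approx(1.5)
        assert interval.sd == pytest.approx(0.70710678, rel=1e-6)
        assert interval.lower == pytest.approx(0.11407, abs=1e-4)
        assert interval.upper == pytest.approx(2.88593, abs=1e-4)

    def test_requires_two_ratios(self):
        with pytest.raises(ValueError):
            reference_interval([1.5])

    def test_log_scale_bounds_are_exponentiated(self):
        interval = reference_interval([1.0, 2.0, 4.0], log_scale=True)
        logs = np.log([1.0, 2.0, 4.0])
        assert interval.lower == pytest.approx(np.exp(logs.mean() - 1.96 * logs.std(ddof=1)))
        assert interval.upper > interval.lower > 0

    def test_coverage_approaches_nominal_five_percent(self, rng):
        """For normal ratios, the fraction outside mean±1.96 SD (recomputed
        per cohort) approaches ~5% as the cohort grows."""
        n = 20_000
        ratios = rng.normal(1.7, 0.5, size=n)
        interval = reference_interval(ratios)
        outside = np.mean((ratios < interval.lower) | (ratios > interval.upper))
        assert outside == pytest.approx(0.05, abs=0.008)


class TestClassify:
    interval = ReferenceInterval(mean=1.69, sd=0.6887755)  # upper ~= 3.04, the study's plasma fixture

    def test_above_upper_is_positive(self):
        assert classify(3.50, self.interval) == POSITIVE

    def test_exactly_upper_is_negative_strict_inequality(self):
        assert classify(self.interval.upper, self.interval) == NEGATIVE

    def test_typical_euploid_is_negative(self):
        assert classify(1.00, self.interval) == NEGATIVE

    def test_below_lower_is_still_negative(self):
        assert classify(0.10, self.interval) == NEGATIVE


class TestEvaluate:
    def test_study_confusion_counts(self):
        # 9 affected with 8 called positive; 27 unaffected with 1 called positive
        predictions = [POSITIVE] * 8 + [NEGATIVE] + [POSITIVE] + [NEGATIVE] * 26
        truth = [TRISOMY18] * 9 + [EUPLOID] * 27
        report = evaluate(predictions, truth)
        assert (report.tp, report.fn, report.fp, report.tn) == (8, 1, 1, 26)
        assert report.sensitivity == pytest.approx(8 / 9)
        assert report.specificity == pytest.approx(26 / 27)

    def test_perfect_and_degenerate_predictions(self):
        truth = [TRISOMY18] * 3 + [EUPLOID] * 4
        perfect = [POSITIVE] * 3 + [NEGATIVE] * 4
        report = evaluate(perfect, truth)
        assert report.sensitivity == 1.0 and report.specificity == 1.0
        all_neg = evaluate([NEGATIVE] * 7, truth)
        assert all_neg.sensitivity == 0.0

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            evaluate(["maybe"], [TRISOMY18])
        with pytest.raises(ValueError):
            evaluate([POSITIVE], ["unknown"])
        with pytest.raises(ValueError):
            evaluate([POSITIVE], [])


class TestClearance:
    def test_no_change_gives_p_one(self):
        pre = [50.0, 60.0, 70.0, 80.0, 90.0]
        assert clearance_test(pre, pre).pvalue == 1.0

    def test_uniform_clearance_ten_pairs_exact(self):
        """Ten uniformly decreasing pairs: exact two-sided p = 2/2^10."""
        pre = [50.0 + i for i in range(10)]
        post = [0.0] * 10
        result = clearance_test(pre, post)
        assert result.exact
        assert result.pvalue == pytest.approx(2 / 2**10)
        assert result.pvalue == pytest.approx(0.002, abs=5e-5)

    def test_sign_flip_symmetry(self):
        pre = [5.0, 9.0, 3.0, 8.0, 7.0, 6.0]
        post = [1.0, 2.0, 4.0, 3.0, 2.0, 9.0]
        forward = clearance_test(pre, post)
        backward = clearance_test(post, pre)
        assert forward.pvalue == backward.pvalue

    def test_matches_scipy_exact_wilcoxon(self, rng):
        """Independent cross-check of the in-package signed-rank test."""
        for _ in range(20):
            pre = rng.random(8) * 10
            post = pre + rng.normal(0, 2, size=8)
            ours = wilcoxon_signed_rank(pre, post)
            ref = scipy.stats.wilcoxon(pre, post, alternative="two-sided", method="exact")
            assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_requires_five_pairs(self):
        with pytest.raises(ValueError):
            clearance_test([1.0, 2.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            clearance_test([1.0] * 6, [0.0] * 5)


def test_large_sample_normal_approximations_close_to_scipy(rng):
    """Beyond the exact-enumeration limits both tests fall back to a
    tie-corrected normal approximation that tracks the reference values."""
    from eggdosage.stats import mann_whitney_u

    x = rng.normal(0, 1, 40)
    y = rng.normal(0.5, 1, 35)
    ours = mann_whitney_u(x, y)
    ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
    assert not ours.exact
    assert ours.pvalue == pytest.approx(ref.pvalue, rel=0.05)

    pre = rng.normal(5, 1, 30)
    post = pre - rng.normal(0.4, 1, 30)
    ours_w = wilcoxon_signed_rank(pre, post)
    ref_w = scipy.stats.wilcoxon(pre, post, alternative="two-sided", correction=True)
    assert not ours_w.exact
    assert ours_w.pvalue == pytest.approx(ref_w.pvalue, rel=0.15, abs=1e-3)
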