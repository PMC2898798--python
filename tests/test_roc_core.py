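"""Empirical and smoothed pAUC primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paucboost import (
    PAUCConfig,
    ScorePair,
    approximate_pauc,
    empirical_fpr_tpr,
    empirical_pauc,
    roc_curve,
    select_thresholds,
    smoothed_band,
)
from paucboost.roc_core import null_pauc, pauc_upper_bound, smoothed_pauc_derivatives

from conftest import pauc_pairwise_oracle


class TestFprTpr:
    def test_direct_count_with_ties_at_threshold(self):
        pair = ScorePair(np.array([1.0, 2, 3, 4]), np.array([3.0, 4, 5, 6]))
        assert empirical_fpr_tpr(pair, 3.0) == (0.5, 1.0)

    def test_threshold_below_everything(self):
        pair = ScorePair(np.array([1.0, 2]), np.array([3.0, 4]))
        assert empirical_fpr_tpr(pair, -10.0) == (1.0, 1.0)

    def test_matches_exhaustive_count_at_order_statistics(self, rng):
        s0, s1 = rng.normal(size=12), rng.normal(size=9)
        pair = ScorePair(s0, s1)
        for c in np.concatenate([s0, s1]):
            fpr, tpr = empirical_fpr_tpr(pair, float(c))
            assert fpr == sum(1 for v in s0 if v >= c) / 12
            assert tpr == sum(1 for v in s1 if v >= c) / 9

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ScorePair(np.array([]), np.array([1.0]))


class TestThresholds:
    def test_exact_attainment_with_ten_controls(self, window):
        pair = ScorePair(np.arange(10.0), np.array([20.0]))
        thr = select_thresholds(pair, window)
        assert thr.alpha2_hat == pytest.approx(0.1)
        assert thr.c2_hat == 9.0  # largest control score

    def test_alpha1_zero_kills_rectangle(self, window):
        pair = ScorePair(np.arange(10.0), np.array([20.0, 0.0]))
        thr = select_thresholds(pair, window)
        assert thr.alpha1_hat == 0.0
        # every case must be judged against a threshold above all controls
        assert thr.c1_strict and thr.c1_hat == 9.0

    def test_equidistant_tie_takes_smaller_fpr(self, window):
        # with 15 controls the attainable FPRs 1/15 and 2/15 are equidistant
        # from 0.1; the conservative rule keeps 1/15
        pair = ScorePair(np.arange(15.0), np.array([20.0]))
        thr = select_thresholds(pair, window)
        assert thr.alpha2_hat == pytest.approx(1 / 15)

    def test_ordering_invariants(self, rng):
        for _ in range(20):
            pair = ScorePair(rng.normal(size=17), rng.normal(size=5))
            cfg = PAUCConfig(0.15, 0.6)
            thr = select_thresholds(pair, cfg)
            assert thr.alpha1_hat <= thr.alpha2_hat
            assert thr.c2_hat <= thr.c1_hat
            assert (thr.alpha1_hat * 17) == pytest.approx(round(thr.alpha1_hat * 17))


class TestEmpiricalPauc:
    def test_perfect_separation_attains_bound(self, window):
        pair = ScorePair(np.arange(20.0), np.arange(20.0) + 100)
        assert empirical_pauc(pair, window) == pytest.approx(0.1)

    def test_reversed_separation_is_zero(self, window):
        pair = ScorePair(np.arange(20.0) + 100, np.arange(20.0))
        assert empirical_pauc(pair, window) == 0.0

    def test_full_window_equals_mann_whitney(self, full_window):
        pair = ScorePair(np.array([1.0, 3]), np.array([2.0, 4]))
        assert empirical_pauc(pair, full_window) == pytest.approx(0.75)

    def test_full_window_matches_sklearn_auc(self, rng, full_window):
        from sklearn.metrics import roc_auc_score

        s0, s1 = rng.normal(size=30), rng.normal(0.7, 1, size=25)
        pair = ScorePair(s0, s1)
        y = np.r_[np.zeros(30), np.ones(25)]
        assert empirical_pauc(pair, full_window) == pytest.approx(
            roc_auc_score(y, np.r_[s0, s1])
        )

    def test_constant_score_is_degenerate_not_error(self, window, full_window):
        pair = ScorePair(np.zeros(10), np.zeros(8))
        assert empirical_pauc(pair, window) == 0.0
        # at the full window every control is at the single attained FPR 1
        assert empirical_pauc(pair, full_window) == 1.0

    @pytest.mark.parametrize("alpha", [(0.0, 0.1), (0.0, 0.5), (0.2, 0.7), (0.0, 1.0)])
    def test_matches_pairwise_oracle(self, rng, alpha):
        cfg = PAUCConfig(*alpha)
        for _ in range(40):
            n0 = int(rng.integers(2, 21))
            n1 = int(rng.integers(2, 21))
            s0 = np.round(rng.normal(size=n0), 1)  # rounding forces ties
            s1 = np.round(rng.normal(0.5, 1, size=n1), 1)
            got = empirical_pauc(ScorePair(s0, s1), cfg)
            want = pauc_pairwise_oracle(list(s0), list(s1), *alpha)
            assert got == pytest.approx(want), (s0, s1)

    def test_monotone_transform_invariance(self, rng, window):
        s0, s1 = rng.normal(size=15), rng.normal(0.5, 1, size=12)
        base = empirical_pauc(ScorePair(s0, s1), window)
        for f in (np.exp, lambda z: z**3, lambda z: 5 * z - 2):
            assert empirical_pauc(ScorePair(f(s0), f(s1)), window) == pytest.approx(base)

    @given(
        s0=st.lists(st.integers(-50, 50), min_size=2, max_size=20),
        s1=st.lists(st.integers(-50, 50), min_size=2, max_size=20),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounded_by_window_width(self, s0, s1):
        cfg = PAUCConfig(0.0, 0.1)
        pair = ScorePair(np.array(s0, float), np.array(s1, float))
        val = empirical_pauc(pair, cfg)
        # alpha2_hat can exceed alpha2 by at most half the FPR grid spacing
        thr = select_thresholds(pair, cfg)
        assert 0.0 <= val <= thr.alpha2_hat + 1e-12


class TestApproximatePauc:
    def test_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            PAUCConfig(0.0, 0.1, sigma=0.0)

    def test_small_sigma_converges_to_empirical(self, rng, window):
        # as sigma -> 0 the level thresholds become the control order
        # statistics and the smoothed TPR hardens, recovering the empirical
        # fan + rectangle value on tie-free data
        s0, s1 = rng.normal(size=15), rng.normal(1, 1, size=15)
        pair = ScorePair(s0, s1)
        for cfg in (window, PAUCConfig(0.2, 0.7)):
            want = empirical_pauc(pair, cfg)
            small = PAUCConfig(cfg.alpha1, cfg.alpha2, sigma=1e-5)
            assert approximate_pauc(pair, small) == pytest.approx(want, abs=1e-6)

    def test_single_tied_pair_contributes_half(self):
        # one case equal to the single window control: Phi(0) = 1/2
        pair = ScorePair(np.array([0.0]), np.array([0.0]))
        got = approximate_pauc(pair, PAUCConfig(0.0, 1.0, sigma=1.0))
        assert got == pytest.approx(0.5)

    def test_tiny_fixed_input_matches_hand_expansion(self):
        # independent evaluation: brentq roots of the smoothed FPR equation
        # per level, then the averaged smoothed TPR over those thresholds
        from scipy.optimize import brentq
        from scipy.stats import norm

        s0 = np.array([0.0, 1.0, 2.0])
        s1 = np.array([0.5, 1.5, 2.5])
        cfg = PAUCConfig(0.0, 1.0, sigma=1.0)
        want = 0.0
        for k in (1, 2, 3):
            level = (k - 0.5) / 3  # half-step targets harden to order statistics
            c = brentq(lambda c: norm.cdf(s0 - c).mean() - level, -15, 15)
            want += norm.cdf(s1 - c).mean() / 3
        assert approximate_pauc(ScorePair(s0, s1), cfg) == pytest.approx(want, abs=1e-9)

    def test_band_thresholds_hit_level_targets_exactly(self, rng):
        from scipy.special import ndtr

        s0 = rng.normal(size=40)
        pair = ScorePair(s0, rng.normal(size=5))
        cfg = PAUCConfig(0.05, 0.3)
        band = smoothed_band(pair, cfg)
        assert band.alpha1_hat == pytest.approx(2 / 40)
        assert band.alpha2_hat == pytest.approx(12 / 40)
        for lvl, c in zip(band.levels, band.thresholds):
            assert ndtr(s0 - c).mean() == pytest.approx(lvl - 0.5 / 40, abs=1e-9)
        # levels start just above the alpha1 level and end at the alpha2 one
        assert band.levels[0] == pytest.approx(3 / 40)
        assert band.levels[-1] == pytest.approx(12 / 40)

    def test_constant_score_approaches_null_value(self, rng):
        # a score collapsing to a constant has the diagonal-ROC pAUC
        pair = ScorePair(1e-9 * rng.normal(size=400), 1e-9 * rng.normal(size=400))
        for cfg in (PAUCConfig(0.0, 0.1), PAUCConfig(0.0, 1.0), PAUCConfig(0.2, 0.6)):
            assert approximate_pauc(pair, cfg) == pytest.approx(
                null_pauc(cfg), abs=2e-3
            )

    def test_scale_invariance_with_sigma(self, rng):
        # multiplying all scores and sigma jointly leaves the value unchanged,
        # which is why the boosting objective can fix sigma = 1
        s0, s1 = rng.normal(size=12), rng.normal(0.5, 1, size=10)
        base = approximate_pauc(ScorePair(s0, s1), PAUCConfig(0.0, 0.2, sigma=1.0))
        for a in (0.3, 2.0, 7.5):
            scaled = approximate_pauc(
                ScorePair(a * s0, a * s1), PAUCConfig(0.0, 0.2, sigma=a)
            )
            assert scaled == pytest.approx(base, rel=1e-9)

    def test_derivatives_match_finite_differences(self, rng):
        # frozen-band objective: only the case scores move with beta
        for cfg in (PAUCConfig(0.0, 0.3), PAUCConfig(0.2, 0.6)):
            F0, F1 = rng.normal(size=12), rng.normal(0.5, 1, size=9)
            f0, f1 = rng.normal(0, 0.5, 12), rng.normal(0, 0.5, 9)
            b = 0.7
            band = smoothed_band(ScorePair(F0 + b * f0, F1 + b * f1), cfg)

            def g(beta):
                return approximate_pauc(
                    ScorePair(F0 + beta * f0, F1 + beta * f1), cfg, band=band
                )

            h = 1e-5
            d1, d2 = smoothed_pauc_derivatives(F1, f1, b, band)
            assert d1 == pytest.approx((g(b + h) - g(b - h)) / (2 * h), abs=1e-7)
            assert d2 == pytest.approx((g(b + h) - 2 * g(b) + g(b - h)) / h**2, abs=1e-4)


class TestRocCurve:
    def test_perfect_separation_passes_through_corner(self):
        pts = roc_curve(ScorePair(np.arange(5.0), np.arange(5.0) + 10))
        assert any(np.allclose(p, (0.0, 1.0)) for p in pts)

    def test_staircase_monotone_and_anchored(self, rng):
        pts = roc_curve(ScorePair(rng.normal(size=15), rng.normal(size=12)))
        assert np.allclose(pts[0], (0, 0)) and np.allclose(pts[-1], (1, 1))
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_identical_tied_scores_stay_on_diagonal(self):
        pts = roc_curve(ScorePair(np.array([1.0, 1, 2, 2]), np.array([1.0, 1, 2, 2])))
        assert np.allclose(pts[:, 0], pts[:, 1])

    def test_trapezoid_area_equals_full_window_pauc(self, rng, full_window):
        # tie-free scores: staircase area equals the Mann-Whitney form
        s0 = rng.permutation(np.arange(0.0, 30.0))[:15]
        s1 = rng.permutation(np.arange(0.5, 30.5))[:12]
        pair = ScorePair(s0, s1)
        pts = roc_curve(pair)
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert area == pytest.approx(empirical_pauc(pair, full_window))


def test_null_and_bound_helpers():
    cfg = PAUCConfig(0.1, 0.4)
    assert pauc_upper_bound(cfg) == pytest.approx(0.3)
    assert null_pauc(cfg) == pytest.approx((0.4**2 - 0.1**2) / 2)
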