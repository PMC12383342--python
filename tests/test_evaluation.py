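"""ROC/DeLong machinery, threshold metrics, calibration, decision curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habitatmil.evaluation import (
    auc_brute_force,
    calibration_curve,
    decision_curve,
    delong_test,
    hosmer_lemeshow,
    roc_auc,
    threshold_metrics,
)


class TestAUC:
    def test_perfect_ranking(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(scores, labels).auc == 1.0

    def test_pair_enumeration_example(self):
        scores = np.array([0.9, 0.3, 0.8, 0.2])
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(scores, labels).auc == 0.75

    def test_sign_reversal_symmetry(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert roc_auc(-scores, labels).auc == pytest.approx(
            1.0 - roc_auc(scores, labels).auc)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_with_ties(self, seed):
        """The midrank AUC equals exhaustive pair enumeration, ties included."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        scores = rng.integers(0, 8, n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels).auc == pytest.approx(
            auc_brute_force(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_ci_clipped_and_contains_point(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = labels + rng.normal(0, 0.5, 100)
        res = roc_auc(scores, labels)
        lo, hi = res.ci95
        assert 0 <= lo <= res.auc <= hi <= 1
        res_logit = roc_auc(scores, labels, ci_method="logit")
        assert 0 < res_logit.ci95[0] < res_logit.ci95[1] < 1


class TestDeLong:
    def test_self_comparison(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.random(60)
        with pytest.warns(UserWarning, match="zero variance"):
            z, p = delong_test(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(7)
        n = 200
        labels = np.repeat([0, 1], n // 2)
        scores = labels + rng.normal(0, 1.0, n)
        analytic = roc_auc(scores, labels).variance
        boots = []
        idx_pos = np.flatnonzero(labels == 1)
        idx_neg = np.flatnonzero(labels == 0)
        for _ in range(2000):
            idx = np.concatenate([rng.choice(idx_pos, idx_pos.size),
                                  rng.choice(idx_neg, idx_neg.size)])
            boots.append(auc_brute_force(scores[idx], labels[idx]))
        emp = np.var(boots, ddof=1)
        assert abs(analytic - emp) / emp < 0.15

    def test_detects_a_real_difference(self):
        rng = np.random.default_rng(2)
        n = 400
        labels = np.repeat([0, 1], n // 2)
        good = labels + rng.normal(0, 0.5, n)
        bad = rng.normal(0, 1, n)
        z, p = delong_test(good, bad, labels)
        assert p < 1e-6 and z > 0

    def test_unpaired_scores_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            delong_test([0.1, 0.2], [0.1], [0, 1])


class TestThresholdMetrics:
    def test_hand_confusion(self):
        # TP=3, FN=1, TN=4, FP=2
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.2, 0.3, 0.4, 0.9, 0.8])
        m = threshold_metrics(scores, labels, 0.5, n_boot=50, seed=0)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(4 / 6)
        assert m.ppv == pytest.approx(0.6)
        assert m.npv == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(0.7)

    def test_all_correct(self):
        labels = np.array([0, 0, 1, 1])
        m = threshold_metrics(np.array([0.1, 0.2, 0.8, 0.9]), labels, 0.5, n_boot=20)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_undefined_ppv_reported_as_missing(self):
        labels = np.array([0, 0, 1, 1])
        m = threshold_metrics(np.array([0.1, 0.1, 0.2, 0.2]), labels, 0.9, n_boot=20)
        assert np.isnan(m.ppv)
        assert m.sensitivity == 0.0

    def test_ci_contains_point_and_narrows_with_n(self):
        rng = np.random.default_rng(3)

        def width(n):
            labels = np.repeat([0, 1], n // 2)
            scores = labels * 0.4 + rng.random(n) * 0.6
            m = threshold_metrics(scores, labels, 0.5, n_boot=300, seed=1)
            lo, hi = m.ci95["accuracy"]
            assert lo - 1e-9 <= m.accuracy <= hi + 1e-9
            return hi - lo

        assert width(1000) < width(100)


class TestHosmerLemeshow:
    def test_df_rule(self):
        rng = np.random.default_rng(0)
        probs = rng.random(200)
        labels = (rng.random(200) < probs).astype(int)
        chi2, df, p = hosmer_lemeshow(probs, labels, groups=10)
        assert df == 8
        assert 0 <= p <= 1

    def test_perfectly_matching_groups(self):
        # ten distinct risk levels, observed rate exactly equal to predicted
        probs = np.repeat(np.linspace(0.05, 0.95, 10), 20)
        labels = np.concatenate([
            np.repeat([1, 0], [int(round(20 * q)), 20 - int(round(20 * q))])
            for q in np.linspace(0.05, 0.95, 10)
        ])
        chi2, df, p = hosmer_lemeshow(probs, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least"):
            hosmer_lemeshow(np.random.random(30), np.zeros(30), groups=10)


class TestCalibration:
    def test_identical_probs_single_point(self):
        rng = np.random.default_rng(1)
        probs = np.full(200, 0.3)
        labels = (rng.random(200) < 0.3).astype(int)
        res = calibration_curve(probs, labels, n_boot=100, seed=0)
        pts = [(m, o) for m, o in zip(res.mean_predicted, res.observed)
               if np.isfinite(m)]
        assert len(pts) == 1
        m, o = pts[0]
        assert m == pytest.approx(0.3)
        assert abs(o - 0.3) < 0.1

    def test_well_calibrated_curve_near_diagonal(self):
        rng = np.random.default_rng(2)
        probs = rng.random(1000)
        labels = (rng.random(1000) < probs).astype(int)
        res = calibration_curve(probs, labels, n_boot=200, seed=0)
        ok = np.isfinite(res.mean_predicted)
        assert np.abs(res.mean_predicted[ok] - res.observed[ok]).max() < 0.15
        # bootstrap band brackets the observed curve
        assert (res.band_lo[ok] <= res.observed[ok] + 1e-9).all()
        assert (res.band_hi[ok] >= res.observed[ok] - 1e-9).all()

    def test_bands_widen_as_n_shrinks(self):
        rng = np.random.default_rng(3)

        def band(n):
            probs = rng.random(n)
            labels = (rng.random(n) < probs).astype(int)
            res = calibration_curve(probs, labels, n_boot=200, seed=0)
            ok = np.isfinite(res.band_hi) & np.isfinite(res.band_lo)
            return np.nanmean(res.band_hi[ok] - res.band_lo[ok])

        assert band(100) > band(1000)


class TestDecisionCurve:
    def test_perfect_classifier_at_half(self):
        labels = np.repeat([0, 1], 50)
        probs = labels.astype(float) * 0.98 + 0.01
        dc = decision_curve(probs, labels, thresholds=[0.5])
        assert dc.net_benefit_model[0] == pytest.approx(0.5)

    def test_treat_all_zero_at_prevalence(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], [70, 30])
        probs = rng.random(100)
        pi = labels.mean()
        dc = decision_curve(probs, labels, thresholds=[pi])
        assert dc.net_benefit_all[0] == pytest.approx(0.0, abs=1e-12)

    def test_treat_none_identically_zero(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 80)
        dc = decision_curve(rng.random(80), labels)
        np.testing.assert_array_equal(dc.net_benefit_none, 0.0)

    def test_net_benefit_bounded_by_prevalence(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 300)
        probs = np.clip(labels * 0.5 + rng.random(300) * 0.5, 0, 1)
        dc = decision_curve(probs, labels)
        assert dc.net_benefit_model.max() <= labels.mean() + 1e-12

    def test_threshold_domain_guard(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], thresholds=[0.0])
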