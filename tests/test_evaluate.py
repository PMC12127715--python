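import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sgascreen.evaluate import (
    EvaluationError,
    calibration_fit,
    detection_rate_at_fpr,
    fixed_fpr_threshold,
    mcnemar_fixed_fpr,
    roc_auc,
)


def brute_force_auc(risks, labels):
    risks = np.asarray(risks, float)
    labels = np.asarray(labels, bool)
    cases = risks[labels]
    controls = risks[~labels]
    wins = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return (wins + 0.5 * ties) / (cases.size * controls.size)


def brute_force_dr(risks, labels, fpr):
    """Exhaustive threshold-scan oracle: the maximal detection rate achievable
    with realised FPR <= fpr over every observed threshold."""
    risks = np.asarray(risks, float)
    labels = np.asarray(labels, bool)
    controls = risks[~labels]
    cases = risks[labels]
    best_dr = 0.0
    for t in np.unique(risks):
        if np.mean(controls >= t) <= fpr:
            best_dr = max(best_dr, np.mean(cases >= t))
    return best_dr


class TestDetectionRate:
    def test_perfect_separation_detects_all(self):
        risks = np.r_[np.zeros(90), np.ones(10)]
        labels = np.r_[np.zeros(90), np.ones(10)].astype(bool)
        for fpr in (0.05, 0.10, 0.3):
            assert detection_rate_at_fpr(risks, labels, fpr).dr_at_fpr == 1.0

    def test_identical_risks_flag_nothing(self):
        risks = np.full(100, 0.2)
        labels = np.r_[np.zeros(80), np.ones(20)].astype(bool)
        ev = detection_rate_at_fpr(risks, labels, 0.10)
        assert ev.dr_at_fpr <= 0.10
        assert ev.fpr_realized <= 0.10

    def test_interleaved_example_matches_exhaustive_scan(self):
        controls = np.arange(1.0, 101.0)
        cases = np.array([15.5, 40.5, 80.5, 92.5, 99.5])
        risks = np.concatenate([controls, cases])
        labels = np.r_[np.zeros(100), np.ones(5)].astype(bool)
        ev = detection_rate_at_fpr(risks, labels, 0.10)
        assert ev.dr_at_fpr == brute_force_dr(risks, labels, 0.10)
        # threshold lands on control value 91 (exactly 10 of 100 controls >= 91)
        assert ev.dr_at_fpr == pytest.approx(2 / 5)

    @settings(deadline=None, max_examples=80)
    @given(st.data())
    def test_threshold_scan_property(self, data):
        n = data.draw(st.integers(12, 60))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        risks = np.round(rng.random(n), 2)  # coarse values force ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            return
        fpr = data.draw(st.sampled_from([0.05, 0.1, 0.25]))
        ev = detection_rate_at_fpr(risks, labels, fpr)
        assert ev.dr_at_fpr == brute_force_dr(risks, labels, fpr)
        assert ev.fpr_realized <= fpr
        assert ev.dr_ci[0] <= ev.dr_at_fpr <= ev.dr_ci[1]

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        risks = rng.random(300)
        labels = rng.random(300) < 0.3
        a = detection_rate_at_fpr(risks, labels, 0.10).dr_at_fpr
        b = detection_rate_at_fpr(np.exp(3 * risks), labels, 0.10).dr_at_fpr
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            detection_rate_at_fpr([0.1, 0.2], [True, True])

    def test_bad_fpr_rejected(self):
        with pytest.raises(EvaluationError):
            fixed_fpr_threshold(np.array([0.1, 0.2]), 0.0)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, ci = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(8)
        risks = rng.random(4000)
        labels = rng.random(4000) < 0.5
        auc, ci = roc_auc(risks, labels)
        assert auc == pytest.approx(0.5, abs=0.03)
        assert ci[0] <= auc <= ci[1]

    def test_worked_pair_counting_example(self):
        auc, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75, abs=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_equals_brute_force_pair_counting(self, data):
        n = data.draw(st.integers(5, 200))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        risks = np.round(rng.random(n), 1)  # heavy ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            return
        auc, _ = roc_auc(risks, labels)
        assert auc == pytest.approx(brute_force_auc(risks, labels), abs=1e-12)

    def test_matches_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(21)
        risks = rng.random(500)
        labels = rng.random(500) < 0.2 + 0.5 * risks
        auc, _ = roc_auc(risks, labels)
        assert auc == pytest.approx(roc_auc_score(labels, risks), abs=1e-12)


class TestCalibrationFit:
    def test_self_calibrated_risks_recover_identity(self):
        rng = np.random.default_rng(31)
        risks = rng.uniform(0.01, 0.5, 50_000)
        labels = rng.random(50_000) < risks
        fit = calibration_fit(risks, labels)
        assert 0.9 <= fit.slope <= 1.1
        assert -0.1 <= fit.intercept <= 0.1
        assert -0.1 <= fit.intercept_in_large <= 0.1

    def test_logit_scale_distortion_recovered(self):
        rng = np.random.default_rng(32)
        risks = rng.uniform(0.02, 0.6, 50_000)
        eta = 2.0 * np.log(risks / (1 - risks))
        labels = rng.random(50_000) < 1 / (1 + np.exp(-eta))
        fit = calibration_fit(risks, labels)
        assert fit.slope == pytest.approx(2.0, abs=0.1)

    def test_constant_risk_is_degenerate(self):
        rng = np.random.default_rng(33)
        risks = np.full(1000, 0.15)
        labels = rng.random(1000) < 0.15
        fit = calibration_fit(risks, labels)
        assert fit.degenerate
        assert np.isnan(fit.slope)
        assert np.isfinite(fit.intercept_in_large)

    def test_boundary_risks_clipped_not_fatal(self):
        rng = np.random.default_rng(34)
        risks = np.r_[0.0, 1.0, rng.uniform(0.1, 0.9, 500)]
        labels = rng.random(502) < np.clip(risks, 0.05, 0.95)
        if labels.all() or not labels.any():
            labels[0] = False
            labels[1] = True
        fit = calibration_fit(risks, labels)
        assert np.isfinite(fit.slope)

    def test_decile_bin_table_shape(self):
        rng = np.random.default_rng(35)
        risks = rng.uniform(0.01, 0.9, 2000)
        labels = rng.random(2000) < risks
        fit = calibration_fit(risks, labels)
        assert set(fit.bin_table.columns) >= {"n", "observed", "expected"}
        assert fit.bin_table["n"].sum() == 2000


class TestMcNemar:
    @staticmethod
    def build(discordant_a, discordant_b, both=20, neither=50, n_controls=300):
        """Construct paired risk vectors realising the wanted discordant counts."""
        rng = np.random.default_rng(41)
        n_cases = discordant_a + discordant_b + both + neither
        labels = np.r_[np.ones(n_cases), np.zeros(n_controls)].astype(bool)
        # controls tile (0,1): threshold at 10% FPR lands at 0.9
        controls = np.linspace(0.001, 0.899, n_controls) * 0 + np.linspace(0.0, 0.89, n_controls)
        risks_a = np.empty(n_cases + n_controls)
        risks_b = np.empty(n_cases + n_controls)
        flags_a = np.r_[np.ones(both), np.ones(discordant_a),
                        np.zeros(discordant_b), np.zeros(neither)].astype(bool)
        flags_b = np.r_[np.ones(both), np.zeros(discordant_a),
                        np.ones(discordant_b), np.zeros(neither)].astype(bool)
        risks_a[:n_cases] = np.where(flags_a, 0.95, 0.1)
        risks_b[:n_cases] = np.where(flags_b, 0.95, 0.1)
        risks_a[n_cases:] = controls
        risks_b[n_cases:] = controls
        return risks_a, risks_b, labels

    def test_identical_flags_p_one(self):
        ra, rb, labels = self.build(0, 0)
        res = mcnemar_fixed_fpr(ra, rb, labels, 0.10)
        assert res.p_value == 1.0

    def test_symmetric_discordance_p_one(self):
        ra, rb, labels = self.build(5, 5)
        res = mcnemar_fixed_fpr(ra, rb, labels, 0.10)
        assert res.exact
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_ten_vs_zero_exact_binomial(self):
        ra, rb, labels = self.build(10, 0)
        res = mcnemar_fixed_fpr(ra, rb, labels, 0.10)
        assert res.discordant_a_only == 10 and res.discordant_b_only == 0
        assert res.exact
        assert res.p_value == pytest.approx(2 * 0.5 ** 10, rel=1e-9)

    def test_large_discordance_uses_chi_square(self):
        ra, rb, labels = self.build(30, 5, both=40, neither=40)
        res = mcnemar_fixed_fpr(ra, rb, labels, 0.10)
        assert not res.exact
        from scipy.stats import chi2

        expected = chi2.sf((abs(30 - 5) - 1) ** 2 / 35, 1)
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_no_cases_rejected(self):
        with pytest.raises(EvaluationError):
            mcnemar_fixed_fpr([0.1, 0.2], [0.1, 0.2], [False, False])
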