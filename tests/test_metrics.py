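"""Calibration and discrimination statistics against closed forms,
brute-force oracles, and parameter-recovery simulations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from csdhval import metrics
from csdhval.metrics import (
    DegeneratePredictorError,
    EstimationError,
    c_statistic,
    calibration_curve,
    calibration_in_the_large,
    calibration_slope,
    concordance,
    model_based_concordance,
    validate_predictions,
)

from conftest import c_index_bruteforce, mbc_bruteforce


class TestCalibrationInTheLarge:
    def test_constant_offset_closed_form(self):
        """With constant predictions the offset-logistic MLE has the closed
        form a = logit(event rate) - logit(p)."""
        p = np.full(8, 0.5)
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0], dtype=float)
        res = calibration_in_the_large(p, y)
        assert res.intercept.estimate == pytest.approx(math.log(1 / 3), abs=1e-6)
        assert res.mean_predicted == 0.5
        assert res.mean_observed == 0.25

    def test_sign_convention_overprediction_negative(self):
        rng = np.random.default_rng(7)
        p = np.full(4000, 0.30)
        y = (rng.random(4000) < 0.10).astype(float)
        res = calibration_in_the_large(p, y)
        assert res.intercept.estimate < 0
        assert res.intercept.ci_low <= res.intercept.estimate <= res.intercept.ci_high

    def test_calibrated_data_give_near_zero_intercept(self):
        rng = np.random.default_rng(11)
        p = expit(rng.normal(-1.5, 1.0, 20000))
        y = (rng.random(20000) < p).astype(float)
        res = calibration_in_the_large(p, y)
        assert abs(res.intercept.estimate) < 0.1

    def test_degenerate_outcomes_rejected(self):
        with pytest.raises(EstimationError):
            calibration_in_the_large(np.array([0.2, 0.3]), np.array([1.0, 1.0]))


class TestCalibrationSlope:
    def test_slope_recovery_unit_and_double(self):
        rng = np.random.default_rng(3)
        lp = rng.normal(-2.0, 1.0, 20000)
        y1 = (rng.random(20000) < expit(lp)).astype(float)
        y2 = (rng.random(20000) < expit(2 * lp)).astype(float)
        assert calibration_slope(expit(lp), y1).slope.estimate == pytest.approx(
            1.0, abs=0.1
        )
        assert calibration_slope(expit(lp), y2).slope.estimate == pytest.approx(
            2.0, abs=0.2
        )

    def test_uninformative_predictions_give_zero_slope(self):
        rng = np.random.default_rng(5)
        p = expit(rng.normal(-1, 1, 20000))
        y = (rng.random(20000) < 0.2).astype(float)  # independent of p
        assert calibration_slope(p, y).slope.estimate == pytest.approx(0.0, abs=0.1)

    def test_constant_lp_is_degenerate(self):
        y = np.array([0, 1, 0, 1], dtype=float)
        with pytest.raises(DegeneratePredictorError):
            calibration_slope(np.full(4, 0.3), y)


class TestConcordance:
    def test_perfect_separation(self):
        assert c_statistic([0.2, 0.8], [0, 1]) == 1.0

    def test_all_tied_predictions(self):
        assert c_statistic([0.4] * 6, [0, 1, 0, 1, 0, 0]) == 0.5

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(4, 120))
            p = np.round(rng.uniform(0.05, 0.95, n), 1)  # coarse grid forces ties
            y = (rng.random(n) < 0.4).astype(float)
            if y.sum() in (0, n):
                y[0], y[1] = 1.0, 0.0
            assert abs(c_statistic(p, y) - c_index_bruteforce(p, y)) <= 1e-12

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self):
        rng = np.random.default_rng(8)
        p = rng.random(300)
        y = (rng.random(300) < p).astype(float)
        a = concordance(p, y, n_boot=200, seed=42)
        b = concordance(p, y, n_boot=200, seed=42)
        assert a.c.ci_low <= a.c.estimate <= a.c.ci_high
        assert a == b

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.05, 0.95, 400)
        y = (rng.random(400) < p).astype(float)
        assert c_statistic(p, y) == pytest.approx(c_statistic(p**2, y), abs=1e-15)


class TestModelBasedConcordance:
    def test_single_pair_closed_form(self):
        assert model_based_concordance([0.2, 0.8]) == pytest.approx(
            0.64 / 0.68, abs=1e-12
        )

    def test_constant_predictions_give_half(self):
        assert model_based_concordance([0.3] * 10) == 0.5

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            n = int(rng.integers(2, 120))
            p = np.round(rng.uniform(0.01, 0.99, n), 1)
            assert abs(model_based_concordance(p) - mbc_bruteforce(p)) <= 1e-12

    def test_not_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0.1, 0.9, 500)
        assert abs(
            model_based_concordance(p) - model_based_concordance(p**2)
        ) > 1e-3

    def test_ignores_outcomes_entirely(self):
        """Permuting y leaves mbc untouched and pushes C toward 0.5."""
        rng = np.random.default_rng(12)
        p = expit(rng.normal(-1, 1.5, 4000))
        y = (rng.random(4000) < p).astype(float)
        mbc = model_based_concordance(p)
        yperm = rng.permutation(y)
        assert model_based_concordance(p) == mbc
        assert c_statistic(p, yperm) == pytest.approx(0.5, abs=0.05)
        assert c_statistic(p, y) > 0.6

    def test_mbc_approximates_c_under_correct_model(self):
        rng = np.random.default_rng(13)
        p = expit(rng.normal(-1.5, 1.2, 60000))
        y = (rng.random(60000) < p).astype(float)
        assert abs(c_statistic(p, y) - model_based_concordance(p)) < 0.01

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        p=st.lists(
            st.floats(min_value=0.01, max_value=0.99), min_size=2, max_size=40
        )
    )
    def test_bounded_and_matches_pairwise_definition(self, p):
        m = model_based_concordance(p)
        assert 0.0 <= m <= 1.0
        assert m == pytest.approx(mbc_bruteforce(p), abs=1e-12)


class TestCalibrationCurve:
    def test_equal_count_bins(self):
        rng = np.random.default_rng(21)
        p = rng.random(1000)
        y = (rng.random(1000) < p).astype(float)
        curve = calibration_curve(p, y, bins=10)
        assert curve.counts.tolist() == [100] * 10
        assert curve.counts.sum() == 1000
        assert not curve.reduced_bins
        assert np.all((curve.observed >= 0) & (curve.observed <= 1))

    def test_reduced_bins_flagged_when_few_distinct_predictions(self):
        rng = np.random.default_rng(22)
        p = rng.choice([0.1, 0.2, 0.4], 200)
        y = (rng.random(200) < p).astype(float)
        curve = calibration_curve(p, y, bins=10)
        assert curve.reduced_bins
        assert len(curve.counts) == 3

    def test_shifted_predictions_sit_below_diagonal(self):
        rng = np.random.default_rng(23)
        truth = rng.uniform(0.05, 0.5, 5000)
        y = (rng.random(5000) < truth).astype(float)
        curve = calibration_curve(truth + 0.1, y, bins=10)
        assert np.all(curve.observed < curve.predicted)

    def test_smoother_returns_proportions(self):
        rng = np.random.default_rng(24)
        p = rng.uniform(0.05, 0.95, 500)
        y = (rng.random(500) < p).astype(float)
        curve = calibration_curve(p, y, method="smoother")
        assert np.all((curve.observed >= 0) & (curve.observed <= 1))
        assert np.all(np.diff(curve.predicted) >= 0)


class TestValidateBundle:
    def test_all_statistics_in_one_result(self):
        rng = np.random.default_rng(31)
        p = expit(rng.normal(-1.8, 1.0, 3000))
        y = (rng.random(3000) < p).astype(float)
        res = validate_predictions(p, y, n_boot=100, seed=1)
        assert res.n == 3000
        assert res.events == int(y.sum())
        assert res.mean_observed == pytest.approx(res.events / res.n)
        assert abs(res.intercept.estimate) < 0.25
        assert res.slope.estimate == pytest.approx(1.0, abs=0.25)
        assert abs(res.c_index.estimate - res.mbc) < 0.05
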