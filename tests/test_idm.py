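"""Isotonic calibration: PAV against the exhaustive block-partition oracle
and scikit-learn, monotonicity/conservation/idempotence properties, and
distortion-recovery behavior of per-subject calibration."""

import logging

import numpy as np
import pytest
from sklearn.isotonic import IsotonicRegression

from ierm.idm import (
    CalibrationSet,
    IsotonicModel,
    calibrate_score,
    calibrate_subject,
    observer_residuals,
    pav_fit,
)
from ierm.model import predict_class
from ierm.synthetic import PowerDistortion, distort_scores
from conftest import exhaustive_isotonic


def make_set(y, w=None, f=None):
    y = np.asarray(y, dtype=float)
    f = np.arange(y.size, dtype=float) if f is None else np.asarray(f, dtype=float)
    return CalibrationSet(f=f, y=y, w=w)


class TestPavFit:
    def test_monotone_input_unchanged(self):
        fit = pav_fit(make_set([0, 1]))
        assert np.array_equal(fit.block_values, [0.0, 1.0])

    def test_single_violation_pooled(self):
        fit = pav_fit(make_set([1, 0]))
        assert np.allclose(fit.block_values, [0.5, 0.5])

    def test_alternating_pooled_to_global_mean(self):
        fit = pav_fit(make_set([1, 0, 1, 0]))
        assert np.allclose(fit.block_values, 0.5)

    def test_weighted_pooling(self):
        fit = pav_fit(make_set([1, 0], w=[3.0, 1.0]))
        assert np.allclose(fit.block_values, 0.75)

    def test_ties_pre_pooled_by_weighted_mean(self):
        fit = pav_fit(make_set([0, 1], f=[0.5, 0.5], w=[1.0, 3.0]))
        assert fit.thresholds.size == 1
        assert fit.block_values[0] == pytest.approx(0.75)

    def test_empty_or_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            CalibrationSet(f=np.array([]), y=np.array([]))
        with pytest.raises(ValueError):
            CalibrationSet(f=np.array([0.1]), y=np.array([1.0]), w=np.array([0.0]))

    def test_residuals_stored_in_item_order(self):
        cal = make_set([1, 0])
        fit = pav_fit(cal)
        assert np.allclose(fit.residuals, [0.5, -0.5])


class TestPavAgainstOracles:
    def random_instances(self, n=200, max_m=10, seed=0):
        rng = np.random.default_rng(seed)
        for _ in range(n):
            m = int(rng.integers(1, max_m + 1))
            y = rng.integers(0, 2, size=m).astype(float)
            w = rng.uniform(0.1, 2.0, size=m)
            yield y, w

    def test_matches_exhaustive_partition_oracle(self):
        for y, w in self.random_instances():
            fit = pav_fit(make_set(y, w=w))
            oracle_fit, oracle_sse = exhaustive_isotonic(y, w)
            sse = float(np.sum(w * (y - fit.block_values) ** 2))
            assert sse == pytest.approx(oracle_sse, abs=1e-9)
            assert np.allclose(fit.block_values, oracle_fit, atol=1e-9)

    def test_matches_sklearn(self):
        for y, w in self.random_instances(n=50, seed=1):
            f = np.arange(y.size, dtype=float)
            fit = pav_fit(make_set(y, w=w, f=f))
            ref = IsotonicRegression().fit(f, y, sample_weight=w).predict(f)
            assert np.allclose(fit.block_values, ref, atol=1e-9)

    def test_monotone_conserving_idempotent(self):
        for y, w in self.random_instances(seed=2):
            fit = pav_fit(make_set(y, w=w))
            assert np.all(np.diff(fit.block_values) >= -1e-12)
            assert np.sum(w * fit.block_values) == pytest.approx(np.sum(w * y))
            # idempotence: refitting the (monotone) fitted values returns them
            refit = pav_fit(make_set(fit.block_values, w=w))
            assert np.allclose(refit.block_values, fit.block_values, atol=1e-12)


class TestCalibrateScore:
    model = IsotonicModel(thresholds=np.array([0.2, 0.8]), block_values=np.array([0.0, 1.0]))

    def test_left_and_right_clamp(self):
        assert calibrate_score(self.model, 0.1) == 0.0
        assert calibrate_score(self.model, 0.9) == 1.0

    def test_right_continuous_step(self):
        assert calibrate_score(self.model, 0.2) == 0.0
        assert calibrate_score(self.model, 0.8) == 1.0
        assert calibrate_score(self.model, 0.5) == 0.0

    def test_constant_model(self):
        const = IsotonicModel(thresholds=np.array([0.5]), block_values=np.array([0.5]))
        assert np.all(calibrate_score(const, np.linspace(0, 1, 7)) == 0.5)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 40).astype(float)
        f = rng.random(40)
        fit = pav_fit(CalibrationSet(f=f, y=y))
        g = np.sort(rng.random(100))
        assert np.all(np.diff(calibrate_score(fit, g)) >= -1e-12)

    def test_json_roundtrip(self):
        restored = IsotonicModel.from_json(self.model.to_json())
        assert np.array_equal(restored.thresholds, self.model.thresholds)
        assert np.array_equal(restored.block_values, self.model.block_values)


def ideal_scores(labels, rng, spread=0.15):
    """Well-calibrated two-unit scores around 0.3/0.7."""
    p1 = np.clip(rng.normal(0.3 + 0.4 * labels, spread), 0.01, 0.99)
    p0 = np.clip(1.0 - p1 + rng.normal(0, 0.02, size=p1.size), 0.01, 0.99)
    return np.stack([p0, p1], axis=1)


class TestCalibrateSubject:
    def test_well_calibrated_scores_are_not_degraded(self):
        rng = np.random.default_rng(0)
        labels = np.tile([0, 1], 120)
        scores = ideal_scores(labels, rng)
        out = calibrate_subject(scores, labels, seed=0)
        acc_raw = np.mean(out["predicted_raw"] == out["labels"])
        acc_cal = np.mean(out["predicted_calibrated"] == out["labels"])
        assert abs(acc_cal - acc_raw) <= 0.02

    def test_cubic_distortion_recovered(self):
        """A p^3 response distortion biases raw argmax; calibration recovers
        at least the uncalibrated accuracy in every one of 10 seeds."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels = np.tile([0, 1], 100)
            distorted = distort_scores(ideal_scores(labels, rng), PowerDistortion(3.0))
            out = calibrate_subject(distorted, labels, seed=seed)
            acc_raw = np.mean(out["predicted_raw"] == out["labels"])
            acc_cal = np.mean(out["predicted_calibrated"] == out["labels"])
            assert acc_cal >= acc_raw

    def test_single_class_split_falls_back_to_identity(self, caplog):
        rng = np.random.default_rng(1)
        labels = np.zeros(20, dtype=int)
        scores = ideal_scores(labels, rng)
        with caplog.at_level(logging.WARNING, logger="ierm.idm"):
            out = calibrate_subject(scores, labels, seed=0)
        assert "identity fallback" in caplog.text
        assert np.allclose(out["calibrated_scores"], out["raw_scores"], atol=1e-12)

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            calibrate_subject(np.full((5, 2), 0.5), np.array([0, 1, 0, 1, 0]))


class TestObserverResiduals:
    def test_perfect_predictions_zero_residual(self):
        labels = np.array([0, 1, 1, 0])
        scores = np.stack([1.0 - labels, labels], axis=1).astype(float)
        res = observer_residuals(scores, labels, np.zeros(4))
        assert res[0] == 0.0

    def test_shift_recovery(self):
        """Scores uniformly shifted +0.2: calibration shrinks the mean
        residual magnitude."""
        rng = np.random.default_rng(3)
        labels = np.tile([0, 1], 100)
        scores = ideal_scores(labels, rng)
        shifted = np.clip(scores + 0.2, 0.01, 0.99)
        out = calibrate_subject(shifted, labels, seed=0)
        sid = np.zeros(out["labels"].size)
        before = observer_residuals(out["raw_scores"], out["labels"], sid)[0]
        after = observer_residuals(out["calibrated_scores"], out["labels"], sid)[0]
        assert abs(after) < abs(before)

    def test_one_entry_per_subject(self):
        rng = np.random.default_rng(0)
        scores = rng.random((30, 2))
        labels = rng.integers(0, 2, 30)
        sids = np.repeat([1, 2, 3], 10)
        assert len(observer_residuals(scores, labels, sids)) == 3

    def test_misalignment_rejected(self):
        with pytest.raises(ValueError):
            observer_residuals(np.zeros((3, 2)), np.zeros(4), np.zeros(3))
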