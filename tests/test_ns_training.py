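"""Losses, paired batches, sensitivity calibration, pseudo-labels, training."""

import numpy as np
import pytest

from bmdetect.cropnet import ModelSpec, build_model
from bmdetect.errors import InfeasibleSensitivityError, PoolExhaustedError
from bmdetect.noising import NoiseConfig
from bmdetect.ns_training import (
    PseudoLabelSet,
    SensitivityCurve,
    TrainingConfig,
    bce_loss,
    calibrate_mu,
    combined_loss,
    pseudo_label,
    sample_paired_batch,
    train_student,
    train_teacher,
)
from tests.conftest import TINY_SPEC


def make_roi_set(pos, neg):
    import pandas as pd

    from bmdetect.candidates import LabeledROISet

    rois = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))]).astype(np.uint8)
    return LabeledROISet(
        rois=rois, labels=labels, provenance=pd.DataFrame(index=range(len(rois)))
    )


class TestLosses:
    def test_bce_analytic_ln2(self):
        assert bce_loss([0.5], [1]) == pytest.approx(np.log(2), rel=1e-6)

    def test_bce_perfect_prediction_near_zero(self):
        assert bce_loss([1.0, 0.0], [1, 0]) < 1e-5

    def test_bce_matches_hand_sum(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, 20)
        y = rng.integers(0, 2, 20)
        hand = -sum(
            yi * np.log(pi) + (1 - yi) * np.log(1 - pi) for pi, yi in zip(p, y)
        ) / 20
        assert bce_loss(p, y) == pytest.approx(hand, rel=1e-9)

    def test_bce_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss([0.5, 0.5], [1])

    def test_combined_lambda_zero_is_labeled_half(self):
        rng = np.random.default_rng(1)
        pl, yl = rng.uniform(0.1, 0.9, 10), rng.integers(0, 2, 10)
        pu, yu = rng.uniform(0.1, 0.9, 6), rng.integers(0, 2, 6)
        assert combined_loss(pl, yl, pu, yu, 0.0) == pytest.approx(bce_loss(pl, yl))
        assert combined_loss(pl, yl, [], [], 0.0) == pytest.approx(bce_loss(pl, yl))

    def test_combined_lambda_one_is_plain_sum(self):
        rng = np.random.default_rng(2)
        pl, yl = rng.uniform(0.1, 0.9, 8), rng.integers(0, 2, 8)
        pu, yu = rng.uniform(0.1, 0.9, 8), rng.integers(0, 2, 8)
        assert combined_loss(pl, yl, pu, yu, 1.0) == pytest.approx(
            bce_loss(pl, yl) + bce_loss(pu, yu)
        )

    def test_combined_affine_in_lambda(self):
        rng = np.random.default_rng(3)
        pl, yl = rng.uniform(0.1, 0.9, 8), rng.integers(0, 2, 8)
        pu, yu = rng.uniform(0.1, 0.9, 8), rng.integers(0, 2, 8)
        l0 = combined_loss(pl, yl, pu, yu, 0.0)
        l1 = combined_loss(pl, yl, pu, yu, 1.0)
        for lam in (0.3, 0.6, 0.8, 2.0):
            assert combined_loss(pl, yl, pu, yu, lam) == pytest.approx(
                l0 + lam * (l1 - l0)
            )

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            combined_loss([0.5], [1], [0.5], [0], -0.1)


class TestPairedBatches:
    def test_exact_composition(self):
        rng = np.random.default_rng(0)
        pools = {
            "pos": np.arange(10, dtype=float)[:, None],
            "neg": -np.arange(5, dtype=float)[:, None],
        }
        batch, names = sample_paired_batch(pools, {"pos": 7, "neg": 7}, rng)
        assert len(batch) == 14
        assert names.count("pos") == 7 and names.count("neg") == 7

    def test_zero_composition_empty(self):
        batch, names = sample_paired_batch(
            {"pos": np.zeros((3, 1))}, {"pos": 0}, np.random.default_rng(0)
        )
        assert len(batch) == 0 and names == []

    def test_empty_pool_raises(self):
        with pytest.raises(PoolExhaustedError):
            sample_paired_batch(
                {"pos": np.zeros((0, 1))}, {"pos": 2}, np.random.default_rng(0)
            )

    def test_sampling_with_replacement_allows_small_pools(self):
        rng = np.random.default_rng(1)
        pools = {"pos": np.ones((2, 1)), "neg": np.zeros((2, 1))}
        batch, _ = sample_paired_batch(pools, {"pos": 50, "neg": 50}, rng)
        assert len(batch) == 100


class TestSensitivityCurve:
    MAXIMA = np.array([0.9, 0.8, 0.7, 0.6, 0.5])

    def test_staircase_counting(self):
        curve = SensitivityCurve(self.MAXIMA)
        assert curve.sensitivity(0.65) == pytest.approx(3 / 5)
        assert curve.sensitivity(0.95) == 0.0
        assert curve.sensitivity(0.4) == 1.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        maxima = rng.uniform(0, 1, 40)
        curve = SensitivityCurve(maxima)
        for t in np.linspace(-0.1, 1.1, 200):
            assert curve.sensitivity(t) == np.mean(maxima > t)

    def test_unmatched_lesions_limit_peak(self):
        curve = SensitivityCurve(np.array([0.9, 0.5, -np.inf, -np.inf]))
        assert curve.peak_sensitivity == 0.5


class TestCalibrateMu:
    def test_worked_example(self):
        """ts=0.8 over five maxima: k=4, mu just below the 4th largest (0.6)."""
        cal = calibrate_mu(SensitivityCurve(TestSensitivityCurve.MAXIMA), ts=0.8)
        assert 0.59 < cal.mu < 0.6
        assert cal.achieved_sensitivity == pytest.approx(0.8)

    def test_full_sensitivity(self):
        cal = calibrate_mu(SensitivityCurve(TestSensitivityCurve.MAXIMA), ts=1.0)
        assert 0.49 < cal.mu < 0.5
        assert cal.achieved_sensitivity == 1.0

    def test_maximality_against_scan(self):
        """mu must be the largest threshold reaching ts: any larger observed
        response must drop the sensitivity below ts."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            maxima = rng.uniform(0, 1, rng.integers(3, 30))
            curve = SensitivityCurve(maxima)
            ts = rng.uniform(0.2, 1.0)
            cal = calibrate_mu(curve, ts)
            assert curve.sensitivity(cal.mu) >= ts
            larger = maxima[maxima > cal.mu]
            if len(larger):
                assert curve.sensitivity(larger.min()) < ts

    def test_infeasible_target_reports_peak(self):
        curve = SensitivityCurve(np.array([0.9, -np.inf]))
        with pytest.raises(InfeasibleSensitivityError) as err:
            calibrate_mu(curve, ts=0.9)
        assert err.value.peak == pytest.approx(0.5)


class TestPseudoLabel:
    class FakeModel:
        def __init__(self, responses):
            self.responses = np.asarray(responses, dtype=np.float32)

        def forward(self, rois):
            return self.responses[: len(rois)]

    def test_strict_inequality_boundary(self):
        """Responses 0.86 and 0.85 at mu=0.85: only the strict excess counts."""
        model = self.FakeModel([0.86, 0.85])
        out = pseudo_label(model, np.zeros((2, 4, 4, 4), np.float32), mu=0.85)
        assert out.labels.tolist() == [1, 0]

    def test_all_below_mu_all_zero(self):
        model = self.FakeModel([0.1, 0.2, 0.3])
        out = pseudo_label(model, np.zeros((3, 4, 4, 4), np.float32), mu=0.9)
        assert not out.labels.any()

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            resp = rng.uniform(0, 1, rng.integers(1, 50))
            mu = rng.uniform(0.05, 0.95)
            out = pseudo_label(
                self.FakeModel(resp), np.zeros((len(resp), 4, 4, 4), np.float32), mu
            )
            np.testing.assert_array_equal(out.labels, (resp > mu).astype(np.uint8))

    def test_mu_domain(self):
        with pytest.raises(ValueError):
            pseudo_label(self.FakeModel([0.5]), np.zeros((1, 4, 4, 4), np.float32), 1.5)


class TestTraining:
    def test_zero_iterations_returns_init(self, separable_rois):
        pos, neg = separable_rois
        lset = make_roi_set(pos, neg)
        cfg = TrainingConfig(iterations=0, teacher_batch=(4, 4), seed=3)
        model = train_teacher(lset, TINY_SPEC, cfg)
        ref = build_model(
            TINY_SPEC, int(np.random.default_rng(3).integers(0, 2**31 - 1))
        )
        for p, q in zip(model.net.params, ref.net.params):
            np.testing.assert_array_equal(p, q)

    def test_separable_classes_learned(self, separable_rois):
        """Bright-blob vs flat ROIs are linearly separable; a short fit must
        reach high training accuracy."""
        pos, neg = separable_rois
        lset = make_roi_set(pos, neg)
        cfg = TrainingConfig(
            iterations=200,
            teacher_batch=(8, 8),
            learning_rate=3e-3,
            seed=0,
            noise=NoiseConfig(elastic_alpha=1.0),
        )
        model = train_teacher(lset, TINY_SPEC, cfg)
        assert model.training_log[-1] < model.training_log[0]
        resp = model.forward(lset.rois)
        acc = ((resp > 0.5).astype(int) == lset.labels).mean()
        assert acc >= 0.95

    def test_training_deterministic(self, separable_rois):
        pos, neg = separable_rois
        lset = make_roi_set(pos, neg)
        cfg = TrainingConfig(iterations=5, teacher_batch=(4, 4), seed=9)
        a = train_teacher(lset, TINY_SPEC, cfg)
        b = train_teacher(lset, TINY_SPEC, cfg)
        for p, q in zip(a.net.params, b.net.params):
            np.testing.assert_array_equal(p, q)

    def test_single_class_pool_rejected(self, separable_rois):
        pos, _ = separable_rois
        lset = make_roi_set(pos, pos[:0])
        with pytest.raises(PoolExhaustedError):
            train_teacher(lset, TINY_SPEC, TrainingConfig(iterations=1))

    def test_student_lambda_zero_matches_teacher_trajectory(self, separable_rois):
        """With lam=0 and no pseudo samples the student objective reduces to
        the teacher objective: same seeds must give identical parameters."""
        pos, neg = separable_rois
        lset = make_roi_set(pos, neg)
        cfg_t = TrainingConfig(iterations=8, teacher_batch=(6, 6), seed=4)
        cfg_s = TrainingConfig(
            iterations=8, teacher_batch=(6, 6), student_batch=(6, 0, 6, 0), lam=0.0, seed=4
        )
        teacher = train_teacher(lset, TINY_SPEC, cfg_t)
        student = train_student(lset, None, TINY_SPEC, cfg_s)
        for p, q in zip(teacher.net.params, student.net.params):
            np.testing.assert_array_equal(p, q)

    def test_student_needs_pseudo_pool_when_required(self, separable_rois):
        pos, neg = separable_rois
        lset = make_roi_set(pos, neg)
        cfg = TrainingConfig(iterations=1, student_batch=(2, 2, 2, 2), seed=0)
        with pytest.raises(PoolExhaustedError):
            train_student(lset, None, TINY_SPEC, cfg)

    def test_student_uses_pseudo_labels(self, separable_rois):
        pos, neg = separable_rois
        lset = make_roi_set(pos[:10], neg[:10])
        pseudo = PseudoLabelSet(
            rois=np.concatenate([pos[10:], neg[10:]]),
            responses=np.concatenate([np.full(30, 0.9), np.full(30, 0.1)]).astype(
                np.float32
            ),
            labels=np.concatenate([np.ones(30), np.zeros(30)]).astype(np.uint8),
        )
        cfg = TrainingConfig(
            iterations=40,
            student_batch=(4, 4, 4, 4),
            learning_rate=3e-3,
            seed=1,
            noise=NoiseConfig(elastic_alpha=1.0),
        )
        model = train_student(lset, pseudo, TINY_SPEC, cfg)
        resp = model.forward(np.concatenate([pos[:5], neg[:5]]))
        assert resp[:5].mean() > resp[5:].mean()


class TestConfigValidation:
    def test_unpaired_teacher_batch_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(teacher_batch=(10, 8))

    def test_unpaired_student_batch_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(student_batch=(5, 5, 4, 5))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(lam=-1.0)
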