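"""FROC/AFP evaluation, matching rules, patient-level cross-validation."""

import numpy as np
import pytest

from bmdetect.errors import InfeasibleSensitivityError, UndefinedRateError
from bmdetect.evaluation import (
    Detection,
    FROCCurve,
    ScoredExam,
    afp_at_sensitivity,
    detect_bm,
    froc,
    match_detections,
    split_cv_by_patient,
)
from bmdetect.phantom import Exam, LesionSpec


def lesion(x, y, z):
    return LesionSpec(center=(float(x), float(y), float(z)), diameter=5.0)


class TestDetectBM:
    def test_threshold_above_max_empty(self):
        centers = np.array([[1.0, 1, 1], [5, 5, 5]])
        assert detect_bm("E", centers, np.array([0.4, 0.6]), threshold=0.6) == []

    def test_threshold_below_min_keeps_all_after_nms(self):
        centers = np.array([[1.0, 1, 1], [10, 10, 10]])
        dets = detect_bm("E", centers, np.array([0.4, 0.6]), threshold=0.0)
        assert len(dets) == 2

    def test_cluster_collapses_to_highest(self):
        """Candidates 1 mm apart: NMS at 1.5 mm keeps only the peak response."""
        centers = np.array([[10.0, 10, 10], [10.0, 10, 11], [10.0, 11, 10]])
        dets = detect_bm("E", centers, np.array([0.5, 0.9, 0.7]), threshold=0.1)
        assert len(dets) == 1
        assert dets[0].response == pytest.approx(0.9)


class TestMatching:
    def test_inclusive_at_exact_tolerance(self):
        """A detection at exactly 1.5 mm counts: 'up to 1.5 mm' is inclusive."""
        dets = [Detection("E", (10.0, 10.0, 11.5), 0.9)]
        detected, fps = match_detections(dets, [lesion(10, 10, 10)])
        assert detected == {0} and fps == []

    def test_just_beyond_tolerance_is_fp(self):
        dets = [Detection("E", (10.0, 10.0, 11.51), 0.9)]
        detected, fps = match_detections(dets, [lesion(10, 10, 10)])
        assert detected == set() and len(fps) == 1

    def test_no_detections(self):
        detected, fps = match_detections([], [lesion(1, 1, 1)])
        assert detected == set() and fps == []

    def test_multiple_detections_count_lesion_once(self):
        dets = [
            Detection("E", (10.0, 10.0, 10.5), 0.9),
            Detection("E", (10.0, 10.5, 10.0), 0.8),
        ]
        detected, fps = match_detections(dets, [lesion(10, 10, 10)])
        assert detected == {0} and fps == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            dets = [
                Detection("E", tuple(c), float(r))
                for c, r in zip(
                    rng.uniform(0, 30, (rng.integers(0, 20), 3)),
                    rng.uniform(0, 1, 20),
                )
            ]
            lesions = [lesion(*c) for c in rng.uniform(0, 30, (rng.integers(0, 20), 3))]
            detected, fps = match_detections(dets, lesions, tol=2.0)
            want_detected = {
                j
                for j, l in enumerate(lesions)
                if any(
                    np.linalg.norm(np.asarray(d.center) - l.center) <= 2.0 for d in dets
                )
            }
            want_fp = [
                d
                for d in dets
                if all(
                    np.linalg.norm(np.asarray(d.center) - l.center) > 2.0
                    for l in lesions
                )
            ]
            assert detected == want_detected
            assert fps == want_fp


def brute_force_froc(scored, thresholds, tol=1.5):
    """Independent re-evaluation: run detect/match at every threshold."""
    n_lesions = sum(len(s.annotations) for s in scored)
    out = []
    for t in thresholds:
        tp = fp = 0
        for s in scored:
            dets = detect_bm(s.exam_id, s.centers, s.responses, t)
            detected, fps = match_detections(dets, s.annotations, tol)
            tp += len(detected)
            fp += len(fps)
        out.append((tp / n_lesions, fp / len(scored)))
    return out


class TestFROC:
    def rand_scored(self, rng, n_exams=4):
        scored = []
        for i in range(n_exams):
            k = int(rng.integers(1, 12))
            scored.append(
                ScoredExam(
                    exam_id=f"E{i}",
                    centers=rng.uniform(0, 40, (k, 3)),
                    responses=rng.uniform(0, 1, k).astype(np.float32),
                    annotations=[
                        lesion(*c) for c in rng.uniform(0, 40, (rng.integers(0, 4), 3))
                    ],
                )
            )
        if not any(s.annotations for s in scored):
            scored[0].annotations.append(lesion(1, 1, 1))
        return scored

    def test_matches_brute_force_reevaluation(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            scored = self.rand_scored(rng)
            curve = froc(scored)
            want = brute_force_froc(scored, curve.thresholds)
            np.testing.assert_allclose(curve.sensitivity, [w[0] for w in want])
            np.testing.assert_allclose(curve.afp, [w[1] for w in want])

    def test_monotonicity(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            curve = froc(self.rand_scored(rng))
            assert np.all(np.diff(curve.sensitivity) >= 0)  # threshold-descending
            assert np.all(np.diff(curve.afp) >= 0)

    def test_perfect_separation_has_ideal_point(self):
        scored = [
            ScoredExam(
                "E0",
                centers=np.array([[10.0, 10, 10], [30.0, 30, 30]]),
                responses=np.array([0.9, 0.2], np.float32),
                annotations=[lesion(10, 10, 10)],
            )
        ]
        curve = froc(scored)
        ideal = (curve.sensitivity == 1.0) & (curve.afp == 0.0)
        assert ideal.any()

    def test_lesion_free_exams_enter_denominator(self):
        scored = [
            ScoredExam(
                "E0",
                centers=np.array([[10.0, 10, 10]]),
                responses=np.array([0.9], np.float32),
                annotations=[],
            ),
            ScoredExam(
                "E1",
                centers=np.array([[10.0, 10, 10]]),
                responses=np.array([0.9], np.float32),
                annotations=[lesion(10, 10, 10)],
            ),
        ]
        curve = froc(scored)
        # at the lowest threshold: 1 TP, 1 FP over 2 exams -> AFP 0.5
        assert curve.afp[-1] == pytest.approx(0.5)
        assert curve.sensitivity[-1] == 1.0

    def test_no_lesions_at_all_rejected(self):
        scored = [
            ScoredExam(
                "E0",
                centers=np.array([[1.0, 1, 1]]),
                responses=np.array([0.5], np.float32),
                annotations=[],
            )
        ]
        with pytest.raises(UndefinedRateError):
            froc(scored)


class TestAFPAtSensitivity:
    def curve(self):
        return FROCCurve(
            thresholds=np.array([0.9, 0.5]),
            sensitivity=np.array([0.8, 0.9]),
            afp=np.array([2.0, 8.0]),
            n_exams=10,
            n_lesions=20,
        )

    def test_exact_operating_point(self):
        assert afp_at_sensitivity(self.curve(), 0.8) == pytest.approx(2.0)
        assert afp_at_sensitivity(self.curve(), 0.9) == pytest.approx(8.0)

    def test_linear_interpolation_midpoint(self):
        assert afp_at_sensitivity(self.curve(), 0.85) == pytest.approx(5.0)

    def test_no_interpolation_takes_first_reaching(self):
        assert afp_at_sensitivity(self.curve(), 0.85, interpolate=False) == pytest.approx(8.0)

    def test_infeasible_raises(self):
        with pytest.raises(InfeasibleSensitivityError):
            afp_at_sensitivity(self.curve(), 0.95)

    def test_matches_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(2, 12))
            sens = np.sort(rng.uniform(0, 1, n))
            afp = np.sort(rng.uniform(0, 20, n))
            curve = FROCCurve(
                thresholds=np.linspace(1, 0, n),
                sensitivity=sens,
                afp=afp,
                n_exams=5,
                n_lesions=9,
            )
            s = rng.uniform(0, sens.max())
            got = afp_at_sensitivity(curve, s, interpolate=False)
            want = afp[np.argmax(sens >= s - 1e-12)]
            assert got == pytest.approx(want)


class TestRunExperiment:
    def test_single_cell_report_layout(self):
        """One sweep cell on a micro cohort: the report must carry a teacher
        and a student AFP column at the requested sensitivities per cell."""
        from bmdetect.candidates import CandidateConfig
        from bmdetect.cropnet import ModelSpec
        from bmdetect.evaluation import run_experiment
        from bmdetect.noising import NoiseConfig
        from bmdetect.ns_training import TrainingConfig
        from bmdetect.phantom import PhantomParams, generate_cohort

        params = PhantomParams(shape=(48, 48, 48), lesion_count_mean=3.0)
        cohort = generate_cohort({1: 6}, {1: 2}, params, seed=21)
        spec = ModelSpec(blocks_per_level=1, roi_edge_mm=8, levels=3, widths=(2, 4, 8))
        config = TrainingConfig(
            iterations=4,
            teacher_batch=(4, 4),
            student_batch=(2, 2, 2, 2),
            learning_rate=1e-3,
            pseudo_cap_per_exam=30,
            noise=NoiseConfig(elastic_alpha=1.0),
        )
        report = run_experiment(
            cohort,
            spec,
            ModelSpec(blocks_per_level=2, roi_edge_mm=8, levels=3, widths=(2, 4, 8)),
            config,
            CandidateConfig(max_candidates=60),
            ts_values=(0.5,),
            sensitivities=(0.3, 0.5),
            folds=2,
            seed=3,
        )
        assert len(report.cells) == 1
        cell = report.cells[0]
        assert list(cell.afp_table.columns) == ["sensitivity", "teacher", "student"]
        assert len(cell.fold_curves_teacher) == 2
        frame = report.to_frame()
        assert {"ts", "lambda", "afp_teacher", "afp_student"} <= set(frame.columns)
        assert (frame["afp_teacher"] >= 0).all()


class TestPatientCV:
    def make_exams(self, multiplicities):
        exams = []
        e = 0
        for pid, k in enumerate(multiplicities):
            for _ in range(k):
                exams.append(Exam(f"E{e}", f"P{pid}", None, [], True))
                e += 1
        return exams

    def test_study_patient_split(self):
        """158 patients into two patient-level bins of 79 each."""
        exams = self.make_exams([1] * 113 + [2] * 33 + [3] * 10 + [4] * 2)
        fold_of = split_cv_by_patient(exams, folds=2, seed=0)
        pat_fold = {}
        for e in exams:
            pat_fold[e.patient_id] = fold_of[e.exam_id]
        counts = np.bincount(list(pat_fold.values()))
        assert counts.tolist() == [79, 79]

    def test_patient_exams_share_fold(self):
        exams = self.make_exams([4, 1, 1, 2])
        fold_of = split_cv_by_patient(exams, folds=2, seed=1)
        p0_folds = {fold_of[e.exam_id] for e in exams if e.patient_id == "P0"}
        assert len(p0_folds) == 1

    def test_partition(self):
        exams = self.make_exams([1] * 11)
        fold_of = split_cv_by_patient(exams, folds=3, seed=2)
        assert set(fold_of) == {e.exam_id for e in exams}
        assert set(fold_of.values()) == {0, 1, 2}

    def test_too_few_patients(self):
        exams = self.make_exams([1, 1])
        with pytest.raises(ValueError):
            split_cv_by_patient(exams, folds=3, seed=0)
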