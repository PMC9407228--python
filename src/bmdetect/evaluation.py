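"""Detection evaluation: FROC curves, AFP-at-sensitivity, patient-level CV.

The operating metric of the whole framework is the free-response ROC: lesion
detection sensitivity (a lesion counts as detected when a detection lies
within 1.5 mm of its centre, inclusive) against the average number of false
positives per exam (AFP).  Lesion-free exams contribute to the AFP
denominator but never to sensitivity.  Cross-validation folds are assigned
per *patient*, never per exam, so no patient straddles training and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .candidates import MATCH_TOL_MM, CandidateConfig
from .cropnet import Classifier, ModelSpec
from .errors import InfeasibleSensitivityError, UndefinedRateError
from .ns_training import ExamROIs, TrainingConfig, ns_loop, prepare_exam_rois
from .phantom import Cohort, Exam, LesionSpec

__all__ = [
    "Detection",
    "FROCCurve",
    "ExperimentReport",
    "detect_bm",
    "match_detections",
    "froc",
    "afp_at_sensitivity",
    "split_cv_by_patient",
    "score_exam",
    "froc_from_scored",
    "run_experiment",
]

#: Shared sensitivity grid for averaging fold curves.
MEAN_CURVE_GRID = np.round(np.arange(0.50, 1.0001, 0.01), 2)


@dataclass(frozen=True)
class Detection:
    exam_id: str
    center: tuple[float, float, float]
    response: float
    matched_lesion: int = -1  # -1: false positive

    def __post_init__(self) -> None:
        if not 0 <= self.response <= 1:
            raise ValueError("detection response must lie in [0, 1]")


@dataclass
class FROCCurve:
    """Operating points (threshold, sensitivity, AFP/exam), threshold-descending."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    afp: np.ndarray
    n_exams: int
    n_lesions: int
    fold: int = -1

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds)
        order = np.argsort(-t, kind="stable")
        self.thresholds = t[order]
        self.sensitivity = np.asarray(self.sensitivity)[order]
        self.afp = np.asarray(self.afp)[order]
        if np.any(np.diff(self.sensitivity) < -1e-12) or np.any(np.diff(self.afp) < -1e-12):
            raise ValueError("sensitivity and AFP must be non-increasing in the threshold")
        if np.any(self.afp < 0):
            raise ValueError("AFP must be >= 0")


def _nms_keep_highest(
    centers: np.ndarray, responses: np.ndarray, radius: float
) -> np.ndarray:
    """Indices surviving NMS: keep the highest response within ``radius`` mm."""
    order = np.lexsort(
        (centers[:, 2], centers[:, 1], centers[:, 0], -responses)
    )
    keep: list[int] = []
    kept_pts: list[np.ndarray] = []
    for i in order:
        p = centers[i]
        if kept_pts and np.min(((np.asarray(kept_pts) - p) ** 2).sum(axis=1)) < radius**2:
            continue
        keep.append(i)
        kept_pts.append(p)
    return np.asarray(sorted(keep), dtype=int)


def detect_bm(
    exam_id: str,
    centers: np.ndarray,
    responses: np.ndarray,
    threshold: float,
    nms_radius: float = MATCH_TOL_MM,
) -> list[Detection]:
    """Candidates with response strictly above the threshold, NMS at 1.5 mm."""
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    responses = np.asarray(responses, dtype=float)
    hot = responses > threshold
    if not hot.any():
        return []
    idx = np.nonzero(hot)[0]
    keep = _nms_keep_highest(centers[idx], responses[idx], nms_radius)
    return [
        Detection(exam_id, tuple(map(float, centers[idx[i]])), float(responses[idx[i]]))
        for i in keep
    ]


def match_detections(
    dets: list[Detection],
    annotations: list[LesionSpec],
    tol: float = MATCH_TOL_MM,
) -> tuple[set[int], list[Detection]]:
    """(detected lesion ids, false-positive detections).

    A lesion is detected iff some detection lies within ``tol`` (inclusive);
    a detection is a false positive iff it is within ``tol`` of no lesion.
    Multiple detections of one lesion count the lesion once and are not FPs.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if not dets:
        return set(), []
    if not annotations:
        return set(), list(dets)
    dpts = np.asarray([d.center for d in dets])
    apts = np.asarray([a.center for a in annotations])
    dist = np.linalg.norm(dpts[:, None, :] - apts[None, :, :], axis=2)
    hit = dist <= tol
    detected = {int(j) for j in np.nonzero(hit.any(axis=0))[0]}
    false_pos = [d for i, d in enumerate(dets) if not hit[i].any()]
    return detected, false_pos


@dataclass
class ScoredExam:
    """Classifier responses on one exam's candidates, ready for FROC pooling."""

    exam_id: str
    centers: np.ndarray
    responses: np.ndarray
    annotations: list[LesionSpec]


def score_exam(model: Classifier, exam_rois: ExamROIs, annotations: list[LesionSpec]) -> ScoredExam:
    resp = model.forward(exam_rois.rois) if len(exam_rois.rois) else np.empty(0)
    return ScoredExam(exam_rois.exam_id, exam_rois.centers, resp, annotations)


def froc(
    scored: list[ScoredExam],
    thresholds: np.ndarray | None = None,
    tol: float = MATCH_TOL_MM,
    nms_radius: float = MATCH_TOL_MM,
    fold: int = -1,
) -> FROCCurve:
    """Pool detections over exams into the FROC staircase.

    Sensitivity pools lesions across exams; AFP divides total false positives
    by the exam count, lesion-free exams included.  By default the threshold
    sweep visits every observed response (plus an above-maximum point), which
    reproduces the exact staircase.
    """
    if not scored:
        raise ValueError("froc needs at least one exam")
    n_lesions = sum(len(s.annotations) for s in scored)
    if n_lesions == 0:
        raise UndefinedRateError("sensitivity undefined: no lesions in the evaluation set")
    n_exams = len(scored)

    # NMS and matching are threshold-independent: compute per-lesion max
    # matched response and the false-positive response multiset once.
    lesion_max: list[float] = []
    fp_resp: list[float] = []
    all_resp: list[float] = []
    for s in scored:
        if len(s.responses) == 0:
            lesion_max.extend([-np.inf] * len(s.annotations))
            continue
        keep = _nms_keep_highest(s.centers, s.responses, nms_radius)
        centers, resp = s.centers[keep], s.responses[keep]
        all_resp.extend(resp.tolist())
        if s.annotations:
            apts = np.asarray([a.center for a in s.annotations])
            dist = np.linalg.norm(centers[:, None, :] - apts[None, :, :], axis=2)
            hit = dist <= tol
            for j in range(len(s.annotations)):
                matched = hit[:, j]
                lesion_max.append(float(resp[matched].max()) if matched.any() else -np.inf)
            fp_mask = ~hit.any(axis=1)
        else:
            fp_mask = np.ones(len(resp), dtype=bool)
        fp_resp.extend(resp[fp_mask].tolist())
    lesion_arr = np.asarray(lesion_max)
    fp_arr = np.asarray(fp_resp)
    if thresholds is None:
        uniq = np.unique(np.asarray(all_resp)) if all_resp else np.asarray([0.5])
        thresholds = np.concatenate([[uniq[-1] + 1.0], uniq[::-1] - 1e-12])
    sens = [(lesion_arr > t).sum() / n_lesions for t in thresholds]
    afp = [(fp_arr > t).sum() / n_exams for t in thresholds]
    return FROCCurve(
        thresholds=np.asarray(thresholds, dtype=float),
        sensitivity=np.asarray(sens),
        afp=np.asarray(afp),
        n_exams=n_exams,
        n_lesions=n_lesions,
        fold=fold,
    )


def froc_from_scored(model: Classifier, exam_rois: list[ExamROIs], exams: list[Exam],
                     fold: int = -1) -> FROCCurve:
    """Score every exam with the model and pool into one FROC curve."""
    by_id = {e.exam_id: e for e in exams}
    scored = [score_exam(model, er, by_id[er.exam_id].annotations) for er in exam_rois]
    return froc(scored, fold=fold)


def afp_at_sensitivity(curve: FROCCurve, s: float, interpolate: bool = True) -> float:
    """AFP of the first operating point reaching sensitivity ``s``.

    With ``interpolate`` the AFP is linearly interpolated between the
    operating points straddling ``s``; otherwise the first point with
    sensitivity >= s is used.
    """
    sens = curve.sensitivity
    afp = curve.afp
    if s > sens.max() + 1e-12:
        raise InfeasibleSensitivityError(s, float(sens.max()))
    # stored arrays are threshold-descending, i.e. sensitivity-ascending:
    # scan from the high-threshold end for the first point reaching s
    idx = None
    for i in range(len(sens)):
        if sens[i] >= s - 1e-12:
            idx = i
            break
    if not interpolate or idx == 0 or sens[idx] <= s + 1e-12:
        return float(afp[idx])
    prev = idx - 1
    if sens[idx] == sens[prev]:
        return float(afp[idx])
    frac = (s - sens[prev]) / (sens[idx] - sens[prev])
    return float(afp[prev] + frac * (afp[idx] - afp[prev]))


def split_cv_by_patient(
    exams: list[Exam], folds: int, seed: int
) -> dict[str, int]:
    """exam_id -> fold, all exams of a patient sharing one fold, patient counts
    per fold differing by at most one."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    patients = sorted({e.patient_id for e in exams})
    if len(patients) < folds:
        raise ValueError(f"{len(patients)} patients cannot fill {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    fold_of_patient = {patients[p]: int(i % folds) for i, p in enumerate(order)}
    return {e.exam_id: fold_of_patient[e.patient_id] for e in exams}


# ---------------------------------------------------------------------------
# experiment driver (desk-scale analog of the hyperparameter sweeps)
# ---------------------------------------------------------------------------


@dataclass
class CellResult:
    """One sweep cell: configuration plus teacher/student AFP table."""

    ts: float
    lam: float
    iterations: int
    labeled_fraction: float
    fold_curves_teacher: list[FROCCurve]
    fold_curves_student: list[FROCCurve]
    afp_table: pd.DataFrame  # rows: sensitivity; columns: teacher, student


@dataclass
class ExperimentReport:
    cells: list[CellResult]
    config: dict
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            for _, r in cell.afp_table.iterrows():
                rows.append(
                    {
                        "ts": cell.ts,
                        "lambda": cell.lam,
                        "iterations": cell.iterations,
                        "labeled_fraction": cell.labeled_fraction,
                        "sensitivity": r["sensitivity"],
                        "afp_teacher": r["teacher"],
                        "afp_student": r["student"],
                    }
                )
        return pd.DataFrame(rows)


def mean_curve(curves: list[FROCCurve], grid: np.ndarray = MEAN_CURVE_GRID) -> pd.DataFrame:
    """Pointwise mean AFP of fold curves on a shared sensitivity grid."""
    cols = {}
    for c in curves:
        vals = []
        for s in grid:
            try:
                vals.append(afp_at_sensitivity(c, float(s)))
            except InfeasibleSensitivityError:
                vals.append(np.nan)
        cols[f"fold{c.fold}"] = vals
    frame = pd.DataFrame(cols, index=grid)
    frame["mean"] = frame.mean(axis=1)
    frame.index.name = "sensitivity"
    return frame


def run_experiment(
    cohort: Cohort,
    teacher_spec: ModelSpec,
    student_spec: ModelSpec,
    config: TrainingConfig,
    cand_config: CandidateConfig = CandidateConfig(),
    ts_values: tuple[float, ...] = (0.90,),
    lam_values: tuple[float, ...] = (1.0,),
    iteration_values: tuple[int, ...] = (1,),
    labeled_fractions: tuple[float, ...] = (1.0,),
    folds: int = 2,
    sensitivities: tuple[float, ...] = (0.80, 0.85, 0.90),
    seed: int = 0,
) -> ExperimentReport:
    """Patient-level cross-validated sweep over (ts, lambda, iterations, labeled fraction).

    For every sweep cell and fold, a teacher and a student are trained on the
    training bin (plus all unlabeled exams) and evaluated on the held-out bin;
    the report holds per-fold FROC curves and the AFP table at the requested
    sensitivities.  Labeled-fraction cells subsample training-bin *patients*
    at random under the seed.
    """
    fold_of = split_cv_by_patient(cohort.labeled, folds, seed)
    edge = teacher_spec.roi_edge_mm
    prepared = {
        e.exam_id: prepare_exam_rois(e, cand_config, edge) for e in cohort.all_exams
    }
    unlabeled_rois = [prepared[e.exam_id] for e in cohort.unlabeled]
    rng = np.random.default_rng(seed)
    cells: list[CellResult] = []
    for ts in ts_values:
        for lam in lam_values:
            for iters in iteration_values:
                for frac in labeled_fractions:
                    t_curves, s_curves = [], []
                    for fold in range(folds):
                        train = [e for e in cohort.labeled if fold_of[e.exam_id] != fold]
                        test = [e for e in cohort.labeled if fold_of[e.exam_id] == fold]
                        if frac < 1.0:
                            pats = sorted({e.patient_id for e in train})
                            keep_n = max(1, int(round(frac * len(pats))))
                            keep = set(
                                np.asarray(pats)[
                                    rng.permutation(len(pats))[:keep_n]
                                ].tolist()
                            )
                            train = [e for e in train if e.patient_id in keep]
                        result = ns_loop(
                            train,
                            cohort.unlabeled,
                            teacher_spec,
                            student_spec,
                            ts=ts,
                            lam=lam,
                            iterations=iters,
                            config=replace(config, seed=int(rng.integers(0, 2**31 - 1))),
                            cand_config=cand_config,
                            prepared=(
                                [prepared[e.exam_id] for e in train],
                                unlabeled_rois,
                            ),
                        )
                        test_rois = [prepared[e.exam_id] for e in test]
                        t_curves.append(
                            froc_from_scored(result.teacher, test_rois, test, fold)
                        )
                        s_curves.append(
                            froc_from_scored(result.model, test_rois, test, fold)
                        )
                    table = pd.DataFrame(
                        {
                            "sensitivity": sensitivities,
                            "teacher": [
                                float(np.mean([afp_at_sensitivity(c, s) for c in t_curves]))
                                for s in sensitivities
                            ],
                            "student": [
                                float(np.mean([afp_at_sensitivity(c, s) for c in s_curves]))
                                for s in sensitivities
                            ],
                        }
                    )
                    cells.append(
                        CellResult(ts, lam, iters, frac, t_curves, s_curves, table)
                    )
    return ExperimentReport(
        cells=cells,
        config={
            "teacher": teacher_spec.name,
            "student": student_spec.name,
            "folds": folds,
            "iterations": config.iterations,
        },
        seed=seed,
    )
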