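"""Sensitivity-calibrated noisy-student training.

The semi-supervised scheme at the heart of the package:

1. a lower-capacity *teacher* (CropNet-b2) is trained on labeled candidate
   ROIs with paired batches and binary cross-entropy, under data noise;
2. the relationship between the response threshold and the teacher's lesion
   detection *sensitivity* on the training data is measured
   (:func:`sensitivity_curve`), and the pseudo-labeling threshold ``mu`` is
   set for a target sensitivity ``ts`` (:func:`calibrate_mu`) — choosing a
   high ``ts`` keeps hard, low-response lesions in the pseudo-positive pool
   at the price of noisier labels;
3. unlabeled candidate ROIs get binary pseudo-labels by strict thresholding
   of the teacher response, ``y_hat = 1 iff response > mu``;
4. a higher-capacity *student* (CropNet-b4) minimizes
   ``bce(labeled) + lambda * bce(pseudo-labeled)`` over mixed paired batches,
   both halves independently noised;
5. optionally the student replaces the teacher and the cycle repeats.

All randomness flows from a single seed through named child streams, so a
run is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .candidates import (
    MATCH_TOL_MM,
    CandidateConfig,
    LabeledROISet,
    detect_candidates,
    extract_roi,
    label_candidates,
    prepare_volume,
)
from .cropnet import Classifier, ModelSpec, build_model, _sigmoid
from .errors import InfeasibleSensitivityError, PoolExhaustedError
from .noising import NoiseConfig, apply_noise_batch
from .phantom import Exam

__all__ = [
    "TrainingConfig",
    "ThresholdCalibration",
    "PseudoLabelSet",
    "SensitivityCurve",
    "ExamROIs",
    "bce_loss",
    "combined_loss",
    "sample_paired_batch",
    "prepare_exam_rois",
    "roi_set_from_exam_rois",
    "train_teacher",
    "train_student",
    "sensitivity_curve",
    "calibrate_mu",
    "pseudo_label",
    "build_pseudo_label_set",
    "ns_loop",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and batch-composition settings.

    Full-scale defaults: Adam at learning rate 5e-5 with decay rates
    (0.9, 0.999), 12,000 batch iterations without early stopping, teacher
    batches of 150 positive + 150 negative ROIs and student batches of
    75 labeled-positive + 75 pseudo-positive + 75 labeled-negative +
    75 pseudo-negative.  The test suite and the desk-scale benchmark override
    these downward.  Paired training requires equal positive/negative counts
    within each half.
    """

    lam: float = 1.0
    learning_rate: float = 5e-5
    beta1: float = 0.9
    beta2: float = 0.999
    iterations: int = 12_000
    teacher_batch: tuple[int, int] = (150, 150)
    student_batch: tuple[int, int, int, int] = (75, 75, 75, 75)
    pseudo_cap_per_exam: int | None = 100
    grad_clip_norm: float | None = 10.0
    warmup_iterations: int = 50
    seed: int = 0
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.teacher_batch[0] != self.teacher_batch[1]:
            raise ValueError("teacher batches must pair positives and negatives")
        lp, pp, ln, pn = self.student_batch
        if lp != ln or pp != pn:
            raise ValueError(
                "student batches must pair labeled pos=neg and pseudo pos=neg"
            )


@dataclass(frozen=True)
class ThresholdCalibration:
    """Result of sensitivity-based threshold selection."""

    target_sensitivity: float
    mu: float
    achieved_sensitivity: float
    per_lesion_max: np.ndarray


@dataclass
class PseudoLabelSet:
    """Unlabeled ROIs with teacher responses and strict-threshold pseudo-labels."""

    rois: np.ndarray
    responses: np.ndarray
    labels: np.ndarray
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (len(self.rois) == len(self.responses) == len(self.labels)):
            raise ValueError("pseudo-label set fields must have equal length")

    def __len__(self) -> int:
        return len(self.rois)

    def to_frame(self) -> pd.DataFrame:
        frame = self.provenance.copy() if self.provenance is not None else pd.DataFrame()
        frame["response"] = self.responses
        frame["pseudo_label"] = self.labels
        return frame


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

_EPS = 1e-7


def bce_loss(responses, labels) -> float:
    """Mean binary cross-entropy, responses clipped away from {0, 1} by eps."""
    responses = np.asarray(responses, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if responses.shape != labels.shape:
        raise ValueError("responses and labels must have equal length")
    p = np.clip(responses, _EPS, 1 - _EPS)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


def combined_loss(resp_l, y_l, resp_u, y_u, lam: float) -> float:
    """Student objective: bce(labeled half) + lambda * bce(pseudo half).

    Each half is mean-reduced separately; with ``lam=0`` the pseudo half may
    be empty and the value equals the labeled-half loss alone.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    loss = bce_loss(resp_l, y_l)
    if len(np.atleast_1d(resp_u)) == 0:
        if lam != 0:
            raise ValueError("pseudo half may only be empty when lambda = 0")
        return loss
    return loss + lam * bce_loss(resp_u, y_u)


# ---------------------------------------------------------------------------
# batches
# ---------------------------------------------------------------------------


def sample_paired_batch(
    pools: dict[str, np.ndarray],
    composition: dict[str, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Sample, with replacement, exactly the requested count from each pool.

    Returns the stacked ROI batch and the per-sample pool names, in a shuffled
    order.  A pool with a positive requested count must be non-empty.
    """
    picked, names = [], []
    for name, count in composition.items():
        if count < 0:
            raise ValueError("composition counts must be >= 0")
        if count == 0:
            continue
        pool = pools.get(name)
        if pool is None or len(pool) == 0:
            raise PoolExhaustedError(f"pool '{name}' is empty but {count} samples requested")
        idx = rng.integers(0, len(pool), size=count)
        picked.append(pool[idx])
        names.extend([name] * count)
    if not picked:
        return np.empty((0,)), []
    batch = np.concatenate(picked, axis=0)
    order = rng.permutation(len(batch))
    return batch[order], [names[i] for i in order]


# ---------------------------------------------------------------------------
# per-exam candidate ROI preparation
# ---------------------------------------------------------------------------


@dataclass
class ExamROIs:
    """Candidate ROIs of one exam, plus annotation-centred ROIs for training."""

    exam_id: str
    patient_id: str
    labeled: bool
    rois: np.ndarray  # (K, e, e, e)
    centers: np.ndarray  # (K, 3) world mm
    cand_labels: np.ndarray  # (K,) vs. ground truth (evaluation/teacher only)
    matched_lesion: np.ndarray  # (K,)
    ann_rois: np.ndarray  # (L, e, e, e) ROIs at annotation centres
    n_lesions: int


def prepare_exam_rois(
    exam: Exam,
    cand_config: CandidateConfig = CandidateConfig(),
    edge: int = 16,
    tol: float = MATCH_TOL_MM,
) -> ExamROIs:
    """Run the candidate stage on one exam and extract every classifier input."""
    vol = prepare_volume(exam)
    cands = detect_candidates(vol, cand_config)
    frame = label_candidates(cands, exam.annotations, tol)
    rois = (
        np.stack([extract_roi(vol, c.center, edge) for c in cands])
        if cands
        else np.empty((0, edge, edge, edge), dtype=np.float32)
    )
    ann_rois = (
        np.stack([extract_roi(vol, a.center, edge) for a in exam.annotations])
        if exam.annotations
        else np.empty((0, edge, edge, edge), dtype=np.float32)
    )
    return ExamROIs(
        exam_id=exam.exam_id,
        patient_id=exam.patient_id,
        labeled=exam.labeled,
        rois=rois,
        centers=np.asarray([c.center for c in cands]).reshape(len(cands), 3),
        cand_labels=frame["label"].to_numpy(),
        matched_lesion=frame["lesion_id"].to_numpy(),
        ann_rois=ann_rois,
        n_lesions=len(exam.annotations),
    )


def roi_set_from_exam_rois(exam_rois: list[ExamROIs]) -> LabeledROISet:
    """Assemble the labeled training set: matched candidates + annotation centres
    as positives, unmatched candidates as negatives."""
    rois, labels, prov = [], [], []
    for er in exam_rois:
        for i in range(len(er.rois)):
            rois.append(er.rois[i])
            labels.append(int(er.cand_labels[i]))
            prov.append((er.exam_id, int(er.matched_lesion[i]), "candidate"))
        for j in range(len(er.ann_rois)):
            rois.append(er.ann_rois[j])
            labels.append(1)
            prov.append((er.exam_id, j, "annotation"))
    edge = exam_rois[0].rois.shape[-1] if exam_rois else 0
    return LabeledROISet(
        rois=np.asarray(rois, dtype=np.float32).reshape(len(rois), edge, edge, edge),
        labels=np.asarray(labels, dtype=np.uint8),
        provenance=pd.DataFrame(prov, columns=["exam_id", "lesion_id", "source"]),
    )


# ---------------------------------------------------------------------------
# optimization core
# ---------------------------------------------------------------------------


def _run_training(
    model: Classifier,
    pool_specs: list[tuple[str, np.ndarray, int, int, float]],
    config: TrainingConfig,
    rng: np.random.Generator,
) -> list[float]:
    """Shared Adam loop.  ``pool_specs``: (name, pool, count, label, weight).

    The gradient of each half of the objective is mean-reduced over that
    half's sample count and scaled by its weight (1 for the labeled half,
    lambda for the pseudo half).
    """
    from ._engine import Adam

    half_sizes: dict[float, int] = {}
    for _, _, count, _, weight in pool_specs:
        half_sizes[weight] = half_sizes.get(weight, 0) + count
    pools = {name: pool for name, pool, _, _, _ in pool_specs}
    composition = {name: count for name, pool, count, _, _ in pool_specs}
    label_of = {name: label for name, _, _, label, _ in pool_specs}
    weight_of = {name: weight for name, _, _, _, weight in pool_specs}

    opt = Adam(model.net.params, lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2,
               clip_norm=config.grad_clip_norm)
    noise_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    dropout_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    batch_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    losses: list[float] = []
    for it in range(config.iterations):
        if config.warmup_iterations > 0:
            # linear learning-rate warmup: the first optimizer steps on a
            # freshly initialized narrow network can otherwise push an entire
            # early layer into the dead-ReLU regime
            opt.lr = config.learning_rate * min(1.0, (it + 1) / config.warmup_iterations)
        batch, names = sample_paired_batch(pools, composition, batch_rng)
        if len(batch) == 0:
            raise PoolExhaustedError("empty batch composition")
        seeds = [int(noise_rng.integers(0, 2**31 - 1)) for _ in range(len(batch))]
        noised = apply_noise_batch(batch, config.noise, seeds)
        y = np.asarray([label_of[n] for n in names], dtype=np.float32)
        w = np.asarray(
            [weight_of[n] / half_sizes[weight_of[n]] for n in names], dtype=np.float32
        )
        z = model.forward_logits(noised, train=True, rng=dropout_rng)
        p = _sigmoid(z)
        # loss for the log: per-half mean bce, pseudo half weighted by lambda
        loss = float(np.sum(w * -(y * np.log(np.clip(p, _EPS, 1)) +
                                  (1 - y) * np.log(np.clip(1 - p, _EPS, 1)))))
        losses.append(loss)
        model.backward((p - y) * w)
        opt.step(model.net.grads)
    return losses


def train_teacher(
    labeled: LabeledROISet, spec: ModelSpec, config: TrainingConfig
) -> Classifier:
    """Fit the teacher by BCE over noised paired batches of labeled ROIs."""
    pos, neg = labeled.positives, labeled.negatives
    if len(pos) == 0 or len(neg) == 0:
        raise PoolExhaustedError("teacher training needs both classes in the labeled set")
    rng = np.random.default_rng(config.seed)
    model = build_model(spec, int(rng.integers(0, 2**31 - 1)))
    np_, nn_ = config.teacher_batch
    model.training_log = _run_training(
        model,
        [("pos", pos, np_, 1, 1.0), ("neg", neg, nn_, 0, 1.0)],
        config,
        rng,
    )
    return model


def train_student(
    labeled: LabeledROISet,
    pseudo: PseudoLabelSet | None,
    spec: ModelSpec,
    config: TrainingConfig,
) -> Classifier:
    """Fit the student on labeled + pseudo-labeled halves weighted by lambda.

    With ``lam=0`` and zero pseudo counts in the composition, the optimization
    trajectory is identical to :func:`train_teacher` with the matching batch
    composition — the unlabeled term vanishes from the objective.
    """
    pos, neg = labeled.positives, labeled.negatives
    if len(pos) == 0 or len(neg) == 0:
        raise PoolExhaustedError("student training needs both labeled classes")
    lp, pp, ln, pn = config.student_batch
    pool_specs = [("labeled_pos", pos, lp, 1, 1.0)]
    if pp > 0:
        if pseudo is None or len(pseudo.rois[pseudo.labels == 1]) == 0:
            raise PoolExhaustedError("pseudo-positive pool is empty")
        pool_specs.append(("pseudo_pos", pseudo.rois[pseudo.labels == 1], pp, 1, config.lam))
    pool_specs.append(("labeled_neg", neg, ln, 0, 1.0))
    if pn > 0:
        if pseudo is None or len(pseudo.rois[pseudo.labels == 0]) == 0:
            raise PoolExhaustedError("pseudo-negative pool is empty")
        pool_specs.append(("pseudo_neg", pseudo.rois[pseudo.labels == 0], pn, 0, config.lam))
    rng = np.random.default_rng(config.seed)
    model = build_model(spec, int(rng.integers(0, 2**31 - 1)))
    model.training_log = _run_training(model, pool_specs, config, rng)
    return model


# ---------------------------------------------------------------------------
# sensitivity calibration and pseudo-labeling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityCurve:
    """Per-lesion maximum responses pooled over all training lesions.

    A lesion with no matched candidate is recorded as ``-inf`` (never
    detectable at any threshold).  ``sensitivity(t)`` is the non-increasing
    staircase ``#{lesions with max response > t} / L``.
    """

    per_lesion_max: np.ndarray

    def __post_init__(self) -> None:
        if len(self.per_lesion_max) == 0:
            raise ValueError("sensitivity curve needs at least one lesion")

    @property
    def n_lesions(self) -> int:
        return len(self.per_lesion_max)

    @property
    def peak_sensitivity(self) -> float:
        return float(np.isfinite(self.per_lesion_max).mean())

    def sensitivity(self, threshold: float) -> float:
        return float((self.per_lesion_max > threshold).mean())

    def staircase(self) -> tuple[np.ndarray, np.ndarray]:
        """(thresholds, sensitivity just below each threshold), descending."""
        finite = np.sort(self.per_lesion_max[np.isfinite(self.per_lesion_max)])[::-1]
        return finite, np.asarray([self.sensitivity(t - 1e-12) for t in finite])


def sensitivity_curve(model: Classifier, exam_rois: list[ExamROIs]) -> SensitivityCurve:
    """Measure the teacher's per-lesion maximum responses on training exams.

    Only lesion-matched candidates can contribute to a per-lesion maximum, so
    inference runs on that small subset.
    """
    maxima: list[float] = []
    for er in exam_rois:
        matched = er.cand_labels == 1
        resp = model.forward(er.rois[matched]) if matched.any() else np.empty(0)
        lesion_ids = er.matched_lesion[matched]
        for lid in range(er.n_lesions):
            mask = lesion_ids == lid
            if mask.any():
                maxima.append(float(resp[mask].max()))
            else:
                maxima.append(-np.inf)
    return SensitivityCurve(per_lesion_max=np.asarray(maxima))


def calibrate_mu(curve: SensitivityCurve, ts: float) -> ThresholdCalibration:
    """Largest threshold whose training sensitivity still reaches ``ts``.

    Under the strict ``response > mu`` rule the k-th largest per-lesion
    maximum (k = ceil(ts * L)) must itself count as detected, so ``mu`` is
    that response reduced by a relative nudge of 1e-9.
    """
    if not 0 < ts <= 1:
        raise ValueError("target sensitivity must lie in (0, 1]")
    if ts > curve.peak_sensitivity:
        raise InfeasibleSensitivityError(ts, curve.peak_sensitivity)
    l = curve.n_lesions
    k = int(np.ceil(ts * l))
    kth = float(np.sort(curve.per_lesion_max)[::-1][k - 1])
    mu = kth - 1e-9 * max(abs(kth), 1e-3)
    achieved = curve.sensitivity(mu)
    assert achieved >= ts
    return ThresholdCalibration(
        target_sensitivity=ts,
        mu=mu,
        achieved_sensitivity=achieved,
        per_lesion_max=curve.per_lesion_max.copy(),
    )


def pseudo_label(model: Classifier, rois: np.ndarray, mu: float) -> PseudoLabelSet:
    """Strict-threshold pseudo-labels on un-noised ROIs: 1 iff response > mu."""
    if not 0 < mu < 1:
        raise ValueError("mu must lie in (0, 1)")
    responses = model.forward(rois) if len(rois) else np.empty(0, dtype=np.float32)
    return PseudoLabelSet(
        rois=np.asarray(rois, dtype=np.float32),
        responses=responses,
        labels=(responses > mu).astype(np.uint8),
    )


def build_pseudo_label_set(
    model: Classifier,
    exam_rois: list[ExamROIs],
    mu: float,
    cap_per_exam: int | None = None,
    ) -> PseudoLabelSet:
    """Pseudo-label the unlabeled exams' candidate ROIs.

    ``cap_per_exam`` keeps only the top-``cap`` candidates per exam by LoG
    rank before inference — the unlabeled candidate sets are by far the
    largest array in a run, and the low-ranked candidates are overwhelmingly
    flat background.
    """
    rois_list, prov = [], []
    for er in exam_rois:
        rois = er.rois if cap_per_exam is None else er.rois[:cap_per_exam]
        centers = er.centers if cap_per_exam is None else er.centers[:cap_per_exam]
        rois_list.append(rois)
        for c in centers:
            prov.append((er.exam_id, c[0], c[1], c[2]))
    if rois_list:
        all_rois = np.concatenate(rois_list, axis=0)
    else:
        all_rois = np.empty((0,), dtype=np.float32)
    out = pseudo_label(model, all_rois, mu)
    out.provenance = pd.DataFrame(prov, columns=["exam_id", "x_mm", "y_mm", "z_mm"])
    return out


# ---------------------------------------------------------------------------
# the iterative loop
# ---------------------------------------------------------------------------


@dataclass
class NSIteration:
    """Artifacts of one teacher->student round."""

    calibration: ThresholdCalibration
    n_pseudo_pos: int
    n_pseudo_neg: int
    teacher: Classifier
    student: Classifier


@dataclass
class NSResult:
    model: Classifier
    teacher: Classifier
    iterations: list[NSIteration]
    labeled_set: LabeledROISet


def ns_loop(
    labeled_exams: list[Exam],
    unlabeled_exams: list[Exam],
    teacher_spec: ModelSpec,
    student_spec: ModelSpec,
    ts: float = 0.90,
    lam: float = 1.0,
    iterations: int = 1,
    config: TrainingConfig = TrainingConfig(),
    cand_config: CandidateConfig = CandidateConfig(),
    prepared: tuple[list[ExamROIs], list[ExamROIs]] | None = None,
) -> NSResult:
    """Full sensitivity-based noisy-student run.

    Round 1 trains the teacher spec on labeled data, calibrates ``mu`` at the
    target training sensitivity ``ts``, pseudo-labels the unlabeled ROIs and
    trains the student spec with unlabeled-loss weight ``lam``.  Each further
    round promotes the student to teacher, re-calibrates ``mu`` and trains a
    fresh student of the same student spec.  With no unlabeled exams and
    ``lam=0`` (zero pseudo counts) the result is plain supervised training of
    the student spec.

    ``prepared`` lets callers reuse candidate ROIs across runs; otherwise the
    candidate stage runs here.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    edge = teacher_spec.roi_edge_mm
    if prepared is not None:
        labeled_rois, unlabeled_rois = prepared
    else:
        labeled_rois = [prepare_exam_rois(e, cand_config, edge) for e in labeled_exams]
        unlabeled_rois = [prepare_exam_rois(e, cand_config, edge) for e in unlabeled_exams]
    labeled_set = roi_set_from_exam_rois(labeled_rois)

    root = np.random.default_rng(config.seed)
    teacher = train_teacher(
        labeled_set, teacher_spec,
        replace(config, seed=int(root.integers(0, 2**31 - 1))),
    )
    config = replace(config, lam=lam)
    rounds: list[NSIteration] = []
    current_teacher = teacher
    student = teacher
    for _ in range(iterations):
        curve = sensitivity_curve(current_teacher, labeled_rois)
        cal = calibrate_mu(curve, ts)
        pseudo = build_pseudo_label_set(
            current_teacher, unlabeled_rois, cal.mu, config.pseudo_cap_per_exam
        )
        student = train_student(
            labeled_set, pseudo, student_spec,
            replace(config, seed=int(root.integers(0, 2**31 - 1))),
        )
        rounds.append(
            NSIteration(
                calibration=cal,
                n_pseudo_pos=int((pseudo.labels == 1).sum()),
                n_pseudo_neg=int((pseudo.labels == 0).sum()),
                teacher=current_teacher,
                student=student,
            )
        )
        current_teacher = student
    return NSResult(
        model=student, teacher=teacher, iterations=rounds, labeled_set=labeled_set
    )
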