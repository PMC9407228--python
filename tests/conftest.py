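"""Shared fixtures: tiny phantoms, ROI sets and desk-scale model specs.

Everything is generated programmatically at session scope so the suite needs
no data files and stays deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from bmdetect.candidates import CandidateConfig
from bmdetect.cropnet import ModelSpec
from bmdetect.noising import NoiseConfig
from bmdetect.ns_training import TrainingConfig, prepare_exam_rois, roi_set_from_exam_rois
from bmdetect.phantom import PhantomParams, render_phantom, sample_lesion_population

#: Tiny CropNet used where only mechanics (not capacity) matter.
TINY_SPEC = ModelSpec(blocks_per_level=1, roi_edge_mm=8, levels=3, widths=(2, 4, 8))


@pytest.fixture(scope="session")
def phantom_params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def small_exam(phantom_params):
    """One rendered 64 mm exam with four lesions."""
    lesions = sample_lesion_population(phantom_params, 4, seed=42)
    return render_phantom(lesions, phantom_params, seed=42, exam_id="E042", patient_id="P042")


@pytest.fixture(scope="session")
def small_exam_rois(small_exam):
    return prepare_exam_rois(small_exam, CandidateConfig(), edge=16)


@pytest.fixture(scope="session")
def tiny_roi_set(phantom_params):
    """Labeled ROI set pooled from three rendered exams (16 mm ROIs)."""
    exams = []
    for seed in (0, 1, 2):
        lesions = sample_lesion_population(phantom_params, 4, seed=seed)
        exams.append(
            render_phantom(lesions, phantom_params, seed, f"E{seed:03d}", f"P{seed:03d}")
        )
    return roi_set_from_exam_rois([prepare_exam_rois(e) for e in exams])


@pytest.fixture(scope="session")
def separable_rois():
    """Trivially separable 8 mm ROI classes: bright centre blob vs. flat noise."""
    rng = np.random.default_rng(5)
    grid = np.meshgrid(*[np.arange(8) - 3.5] * 3, indexing="ij")
    r2 = sum(g**2 for g in grid)
    blob = np.exp(-r2 / (2 * 2.0**2)).astype(np.float32)
    pos = np.clip(
        0.2 + 0.7 * blob[None] + 0.03 * rng.standard_normal((40, 8, 8, 8)), 0, 1
    ).astype(np.float32)
    neg = np.clip(0.2 + 0.03 * rng.standard_normal((40, 8, 8, 8)), 0, 1).astype(np.float32)
    return pos, neg


@pytest.fixture()
def fast_training_config() -> TrainingConfig:
    return TrainingConfig(
        iterations=60,
        teacher_batch=(8, 8),
        student_batch=(4, 4, 4, 4),
        learning_rate=3e-3,
        seed=11,
        noise=NoiseConfig(elastic_alpha=1.0, elastic_sigma=4.0),
        pseudo_cap_per_exam=50,
    )
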