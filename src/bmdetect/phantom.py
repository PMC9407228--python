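"""Synthetic contrast-enhanced brain phantom cohorts.

The clinical cohorts this framework was designed around are private, so this
module generates exam cohorts with the same *statistical* structure: a labeled
arm and a larger unlabeled arm with disjoint patients, several exams per
patient, a handful of small enhancing lesions per exam (truncated log-normal
diameters calibrated to a mean of 5.45 mm, sd 2.67 mm), and tubular vessel-like
distractors — the dominant false-positive mode of enhancing-lesion detectors.

A phantom volume is built as::

    smooth ellipsoidal "brain" background
    + hyperintense Gaussian-profile vessels (random smooth polylines)
    + soft-edged hyperintense spheres (the lesions)
    + Rician-like noise (magnitude of a complex Gaussian perturbation)

It deliberately omits anatomy (tissue classes, skull, bias fields); see
docs/methods.md for what that does and does not let the test suite show.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .errors import PlacementError
from .volume_io import Volume3D

__all__ = [
    "LesionSpec",
    "PhantomParams",
    "Exam",
    "Cohort",
    "solve_truncated_lognormal",
    "sample_diameters",
    "sample_lesion_population",
    "render_phantom",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "LABELED_MULTIPLICITIES",
    "UNLABELED_MULTIPLICITIES",
]

#: Patient -> exam-count multiplicity tables of the study cohorts: the labeled
#: arm has 158 patients / 217 exams, the unlabeled arm 867 patients / 1247 exams.
LABELED_MULTIPLICITIES = {1: 113, 2: 33, 3: 10, 4: 2}
UNLABELED_MULTIPLICITIES = {1: 579, 2: 208, 3: 68, 4: 12}


@dataclass(frozen=True)
class LesionSpec:
    """A single spherical enhancing lesion.

    ``center`` is in world mm, ``diameter`` in mm (the framework targets
    lesions below 15 mm), ``contrast`` is the intensity uplift relative to the
    local background (dimensionless, > 0).
    """

    center: tuple[float, float, float]
    diameter: float
    contrast: float = 0.5

    def __post_init__(self) -> None:
        if not (2.0 <= self.diameter < 15.0):
            raise ValueError(f"lesion diameter must lie in [2, 15) mm, got {self.diameter}")
        if self.contrast <= 0:
            raise ValueError("lesion contrast must be positive")


@dataclass(frozen=True)
class PhantomParams:
    """Generator configuration.

    Defaults are desk-scale: a 64 mm cubic grid at 1 mm spacing keeps every
    downstream stage CPU-testable; a full-brain grid (~192 mm) is a parameter
    away.  Diameter targets are post-truncation moments on [2, 14] mm.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_count_mean: float = 4.29
    diameter_bounds: tuple[float, float] = (2.0, 14.0)
    diameter_mean: float = 5.45
    diameter_sd: float = 2.67
    lesion_contrast_range: tuple[float, float] = (0.35, 0.8)
    min_separation_mm: float = 8.0
    vessel_count_range: tuple[int, int] = (3, 8)
    vessel_radius_range: tuple[float, float] = (0.5, 1.5)
    vessel_contrast_range: tuple[float, float] = (0.3, 0.7)
    background_intensity: float = 0.4
    background_texture_amp: float = 0.05
    background_texture_sigma: float = 6.0
    noise_sigma: float = 0.03
    brain_axes_fraction: float = 0.44  # ellipsoid semi-axes as fraction of grid extent
    placement_margin_mm: float = 2.0
    max_placement_retries: int = 200

    def __post_init__(self) -> None:
        a, b = self.diameter_bounds
        if not (a < b):
            raise ValueError("diameter bounds must be a non-empty interval")
        if not (a < self.diameter_mean < b):
            raise ValueError("post-truncation diameter mean target must lie inside the bounds")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    # --- geometry helpers -------------------------------------------------

    def extent_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    def brain_center_mm(self) -> np.ndarray:
        return self.extent_mm() / 2.0

    def brain_semi_axes_mm(self) -> np.ndarray:
        return self.extent_mm() * self.brain_axes_fraction

    def inside_brain(self, points_mm: np.ndarray, margin_mm: float = 0.0) -> np.ndarray:
        """Boolean test for world points inside the (margin-eroded) brain ellipsoid."""
        pts = np.atleast_2d(points_mm)
        axes = np.maximum(self.brain_semi_axes_mm() - margin_mm, 1e-6)
        rho = np.square((pts - self.brain_center_mm()) / axes).sum(axis=1)
        return rho <= 1.0


@dataclass
class Exam:
    """One imaging exam: a volume plus its ground-truth lesions.

    For unlabeled exams the ground truth is retained (the generator knows it)
    but ``labeled`` is False: training code must treat annotations of such
    exams as hidden; evaluation may still use them.
    """

    exam_id: str
    patient_id: str
    volume: Volume3D | None
    annotations: list[LesionSpec]
    labeled: bool
    seeds: dict = field(default_factory=dict)


@dataclass
class Cohort:
    labeled: list[Exam]
    unlabeled: list[Exam]

    def __post_init__(self) -> None:
        ids = [e.exam_id for e in self.labeled + self.unlabeled]
        if len(set(ids)) != len(ids):
            raise ValueError("exam ids must be unique within a cohort")
        lp = {e.patient_id for e in self.labeled}
        up = {e.patient_id for e in self.unlabeled}
        if lp & up:
            raise ValueError(f"labeled/unlabeled patient sets overlap: {sorted(lp & up)[:5]}")

    @property
    def all_exams(self) -> list[Exam]:
        return list(self.labeled) + list(self.unlabeled)


# ---------------------------------------------------------------------------
# Diameter distribution: truncated log-normal calibrated by moment matching
# ---------------------------------------------------------------------------


def _truncated_lognormal_moments(mu: float, sigma: float, a: float, b: float) -> tuple[float, float]:
    """Mean and sd of a log-normal(mu, sigma) conditioned on [a, b]."""
    alpha = (np.log(a) - mu) / sigma
    beta = (np.log(b) - mu) / sigma
    z = norm.cdf(beta) - norm.cdf(alpha)
    if z <= 0:
        return np.nan, np.nan

    def raw(k: int) -> float:
        return float(
            np.exp(k * mu + 0.5 * k * k * sigma * sigma)
            * (norm.cdf(beta - k * sigma) - norm.cdf(alpha - k * sigma))
            / z
        )

    m1 = raw(1)
    m2 = raw(2)
    return m1, float(np.sqrt(max(m2 - m1 * m1, 0.0)))


@lru_cache(maxsize=32)
def solve_truncated_lognormal(
    mean: float, sd: float, low: float, high: float
) -> tuple[float, float]:
    """Underlying (mu, sigma) whose [low, high]-truncated log-normal hits (mean, sd).

    Solved numerically; the printed cohort statistics give only the moments,
    not the family, so the family choice is a modelling decision.
    """
    from scipy.optimize import least_squares

    def resid(p):
        m, s = _truncated_lognormal_moments(p[0], np.exp(p[1]), low, high)
        if not np.isfinite(m):
            return [1e3, 1e3]
        return [m - mean, s - sd]

    # start from the untruncated log-normal moment match
    s0 = np.sqrt(np.log(1 + (sd / mean) ** 2))
    m0 = np.log(mean) - 0.5 * s0 * s0
    sol = least_squares(resid, [m0, np.log(s0)], xtol=1e-14, ftol=1e-14)
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    m, s = _truncated_lognormal_moments(mu, sigma, low, high)
    if abs(m - mean) > 1e-3 or abs(s - sd) > 1e-2:
        raise RuntimeError(
            f"moment matching failed: wanted ({mean}, {sd}), got ({m:.4f}, {s:.4f})"
        )
    return mu, sigma


def sample_diameters(params: PhantomParams, count: int, rng: np.random.Generator) -> np.ndarray:
    """Exact inverse-CDF draws from the calibrated truncated log-normal."""
    if count == 0:
        return np.empty(0)
    low, high = params.diameter_bounds
    mu, sigma = solve_truncated_lognormal(params.diameter_mean, params.diameter_sd, low, high)
    alpha = (np.log(low) - mu) / sigma
    beta = (np.log(high) - mu) / sigma
    u = rng.uniform(norm.cdf(alpha), norm.cdf(beta), size=count)
    return np.exp(mu + sigma * norm.ppf(u))


# ---------------------------------------------------------------------------
# Lesion placement and rendering
# ---------------------------------------------------------------------------


def sample_lesion_population(
    params: PhantomParams, count: int, seed: int
) -> list[LesionSpec]:
    """Draw ``count`` lesions: calibrated diameters, uniform centres in the brain mask.

    Centres keep a minimum pairwise separation (default 8 mm) so the 1.5 mm
    detection-matching tolerance is never ambiguous, and stay inside the brain
    ellipsoid with a margin of the lesion radius plus ``placement_margin_mm``.
    """
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    rng = np.random.default_rng(seed)
    diameters = sample_diameters(params, count, rng)
    contrasts = rng.uniform(*params.lesion_contrast_range, size=count)
    centers: list[np.ndarray] = []
    ext = params.extent_mm()
    for i in range(count):
        margin = diameters[i] / 2.0 + params.placement_margin_mm
        placed = False
        for _ in range(params.max_placement_retries):
            cand = rng.uniform(0, 1, size=3) * ext
            if not params.inside_brain(cand, margin_mm=margin)[0]:
                continue
            if centers and np.min(
                np.linalg.norm(np.asarray(centers) - cand, axis=1)
            ) < params.min_separation_mm:
                continue
            centers.append(cand)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place lesion {i + 1}/{count} after "
                f"{params.max_placement_retries} retries"
            )
    return [
        LesionSpec(center=tuple(map(float, c)), diameter=float(d), contrast=float(k))
        for c, d, k in zip(centers, diameters, contrasts)
    ]


def _world_grids(params: PhantomParams) -> list[np.ndarray]:
    return np.meshgrid(
        *[np.arange(n) * s for n, s in zip(params.shape, params.spacing)], indexing="ij"
    )


def _render_background(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    gx, gy, gz = _world_grids(params)
    c = params.brain_center_mm()
    axes = params.brain_semi_axes_mm()
    rho = np.sqrt(
        ((gx - c[0]) / axes[0]) ** 2 + ((gy - c[1]) / axes[1]) ** 2 + ((gz - c[2]) / axes[2]) ** 2
    )
    # soft brain edge, ~1 voxel wide in normalized-radius units
    mask = 1.0 / (1.0 + np.exp((rho - 1.0) / 0.02))
    vol = params.background_intensity * mask
    if params.background_texture_amp > 0:
        texture = ndimage.gaussian_filter(
            rng.standard_normal(params.shape), params.background_texture_sigma
        )
        sd = texture.std()
        if sd > 0:
            vol += params.background_texture_amp * (texture / sd) * mask
    return vol.astype(np.float32)


def _render_vessels(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Random smooth polylines splatted as impulses, then blurred to Gaussian tubes."""
    vol = np.zeros(params.shape, dtype=np.float32)
    n_vessels = int(rng.integers(params.vessel_count_range[0], params.vessel_count_range[1] + 1))
    spacing = np.asarray(params.spacing)
    for _ in range(n_vessels):
        radius = rng.uniform(*params.vessel_radius_range)
        contrast = rng.uniform(*params.vessel_contrast_range)
        # smooth random-walk polyline inside the brain
        for _attempt in range(20):
            start = rng.uniform(0, 1, 3) * params.extent_mm()
            if params.inside_brain(start, margin_mm=2.0)[0]:
                break
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        pts = [start.copy()]
        pos = start.copy()
        step = 0.5  # mm
        for _ in range(int(60 / step)):
            direction += 0.15 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pos = pos + step * direction
            if not params.inside_brain(pos, margin_mm=1.0)[0]:
                break
            pts.append(pos.copy())
        if len(pts) < 4:
            continue
        impulses = np.zeros(params.shape, dtype=np.float32)
        idx = np.rint(np.asarray(pts) / spacing).astype(int)
        idx = np.clip(idx, 0, np.asarray(params.shape) - 1)
        np.add.at(impulses, tuple(idx.T), 1.0)
        tube = ndimage.gaussian_filter(impulses, sigma=radius / spacing)
        peak = tube.max()
        if peak > 0:
            vol += tube * (contrast / peak)
    return vol


def _render_lesions(params: PhantomParams, lesions: list[LesionSpec]) -> np.ndarray:
    vol = np.zeros(params.shape, dtype=np.float32)
    spacing = np.asarray(params.spacing)
    edge_w = 0.4  # mm, soft lesion boundary width
    for les in lesions:
        r = les.diameter / 2.0
        c = np.asarray(les.center)
        lo = np.maximum(np.floor((c - r - 4 * edge_w) / spacing).astype(int), 0)
        hi = np.minimum(
            np.ceil((c + r + 4 * edge_w) / spacing).astype(int) + 1, np.asarray(params.shape)
        )
        if np.any(lo >= hi):
            raise ValueError(f"lesion at {les.center} lies outside the volume extent")
        sub = np.meshgrid(
            *[np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)], indexing="ij"
        )
        dist = np.sqrt(sum((g - ci) ** 2 for g, ci in zip(sub, c)))
        vol[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]] += les.contrast / (
            1.0 + np.exp((dist - r) / edge_w)
        )
    return vol


def render_phantom(
    lesions: list[LesionSpec],
    params: PhantomParams,
    seed: int,
    exam_id: str = "E0000",
    patient_id: str = "P0000",
    labeled: bool = True,
) -> Exam:
    """Rasterize one exam volume; two independent sub-seeds (structure, noise) are logged."""
    ext = params.extent_mm()
    for les in lesions:
        if np.any(np.asarray(les.center) < 0) or np.any(np.asarray(les.center) > ext):
            raise ValueError(f"lesion centre {les.center} outside volume extent {tuple(ext)}")
    root = np.random.default_rng(seed)
    structure_seed, noise_seed = (int(s) for s in root.integers(0, 2**31 - 1, size=2))
    rng_structure = np.random.default_rng(structure_seed)
    vol = _render_background(params, rng_structure)
    vol += _render_vessels(params, rng_structure)
    if lesions:
        vol += _render_lesions(params, lesions)
    if params.noise_sigma > 0:
        rng_noise = np.random.default_rng(noise_seed)
        n1 = rng_noise.standard_normal(params.shape).astype(np.float32)
        n2 = rng_noise.standard_normal(params.shape).astype(np.float32)
        s = params.noise_sigma
        vol = np.sqrt((vol + s * n1) ** 2 + (s * n2) ** 2)
    volume = Volume3D(vol.astype(np.float32), params.spacing, (0.0, 0.0, 0.0))
    return Exam(
        exam_id=exam_id,
        patient_id=patient_id,
        volume=volume,
        annotations=list(lesions),
        labeled=labeled,
        seeds={"structure": structure_seed, "noise": noise_seed},
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _expand_multiplicities(mult: dict[int, int]) -> list[int]:
    out = []
    for exams_per_patient, n_patients in sorted(mult.items()):
        if n_patients < 0 or exams_per_patient < 0:
            raise ValueError("multiplicity counts must be >= 0")
        out.extend([exams_per_patient] * n_patients)
    return out


def generate_cohort(
    labeled_multiplicities: dict[int, int],
    unlabeled_multiplicities: dict[int, int],
    params: PhantomParams,
    seed: int,
    render: bool = True,
) -> Cohort:
    """Generate both cohort arms from patient->exam-count multiplicity tables.

    Patient ids are prefixed ``PL``/``PU`` so the two arms are disjoint by
    construction.  Lesion counts per exam are Poisson with the configured mean;
    lesion-free exams are allowed (they exercise the false-positive denominator).
    Repeated exams of one patient draw fresh lesions: the source statistics are
    reported per patient, but training operates per exam, so lesions are
    regenerated per exam (a declared divergence, see docs/methods.md).

    With ``render=False`` only the manifest and ground truth are generated
    (``volume`` is None) — enough for cohort arithmetic and split logic.
    """
    rng = np.random.default_rng(seed)

    def build_arm(mult: dict[int, int], prefix: str, labeled: bool, offset: int) -> list[Exam]:
        exams: list[Exam] = []
        eidx = offset
        for pidx, n_exams in enumerate(_expand_multiplicities(mult)):
            patient_id = f"{prefix}{pidx:04d}"
            for _ in range(n_exams):
                exam_seed = int(rng.integers(0, 2**31 - 1))
                n_lesions = int(rng.poisson(params.lesion_count_mean))
                lesions = sample_lesion_population(params, n_lesions, exam_seed)
                exam_id = f"E{eidx:05d}"
                eidx += 1
                if render:
                    exam = render_phantom(
                        lesions, params, exam_seed, exam_id, patient_id, labeled
                    )
                else:
                    exam = Exam(exam_id, patient_id, None, lesions, labeled,
                                seeds={"exam": exam_seed})
                exams.append(exam)
        return exams

    labeled_exams = build_arm(labeled_multiplicities, "PL", True, 0)
    unlabeled_exams = build_arm(
        unlabeled_multiplicities, "PU", False, len(labeled_exams)
    )
    return Cohort(labeled=labeled_exams, unlabeled=unlabeled_exams)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write volumes (.nii.gz), annotations CSV and a cohort manifest CSV."""
    import os

    from .volume_io import write_volume

    os.makedirs(out_dir, exist_ok=True)
    ann_rows, manifest_rows = [], []
    for exam in cohort.all_exams:
        if exam.volume is not None:
            write_volume(exam.volume, os.path.join(out_dir, f"{exam.exam_id}.nii.gz"))
        for lid, les in enumerate(exam.annotations):
            ann_rows.append(
                {
                    "exam_id": exam.exam_id,
                    "patient_id": exam.patient_id,
                    "lesion_id": lid,
                    "x_mm": les.center[0],
                    "y_mm": les.center[1],
                    "z_mm": les.center[2],
                    "diameter_mm": les.diameter,
                }
            )
        manifest_rows.append(
            {
                "exam_id": exam.exam_id,
                "patient_id": exam.patient_id,
                "labeled": exam.labeled,
                **{f"seed_{k}": v for k, v in exam.seeds.items()},
            }
        )
    pd.DataFrame(
        ann_rows,
        columns=["exam_id", "patient_id", "lesion_id", "x_mm", "y_mm", "z_mm", "diameter_mm"],
    ).to_csv(os.path.join(out_dir, "annotations.csv"), index=False)
    pd.DataFrame(manifest_rows).to_csv(os.path.join(out_dir, "manifest.csv"), index=False)


def read_cohort(in_dir) -> Cohort:
    """Load a cohort written by :func:`write_cohort` (volumes optional)."""
    import os

    from .volume_io import read_volume

    manifest = pd.read_csv(os.path.join(in_dir, "manifest.csv"))
    ann = pd.read_csv(os.path.join(in_dir, "annotations.csv"))
    labeled, unlabeled = [], []
    for _, row in manifest.iterrows():
        exam_id = str(row["exam_id"])
        vol_path = os.path.join(in_dir, f"{exam_id}.nii.gz")
        volume = read_volume(vol_path) if os.path.exists(vol_path) else None
        sub = ann[ann["exam_id"] == exam_id].sort_values("lesion_id")
        lesions = [
            LesionSpec(center=(r["x_mm"], r["y_mm"], r["z_mm"]), diameter=r["diameter_mm"])
            for _, r in sub.iterrows()
        ]
        seeds = {
            c.removeprefix("seed_"): int(row[c])
            for c in manifest.columns
            if c.startswith("seed_") and pd.notna(row[c])
        }
        exam = Exam(exam_id, str(row["patient_id"]), volume, lesions, bool(row["labeled"]), seeds)
        (labeled if exam.labeled else unlabeled).append(exam)
    return Cohort(labeled=labeled, unlabeled=unlabeled)
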