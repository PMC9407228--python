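"""Data-noising for training ROIs: elastic deformation, gamma, rotations, flips.

Input noise is what lets the student model generalize beyond the teacher's
pseudo-labels.  The pipeline composes, in order: Simard-type random elastic
deformation -> random gamma correction -> random axis-aligned rotation/flip.
Magnitudes default to values that keep a centred lesion within the 1.5 mm
matching tolerance of the cube centre (label preservation), since the noising
must never move a positive ROI out of "positive" semantics.

Pseudo-labeling inference always runs on *un-noised* ROIs; noise enters only
through the training losses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DimensionError

__all__ = [
    "NoiseConfig",
    "elastic_deform",
    "gamma_correct",
    "rotate_flip",
    "apply_noise",
    "apply_noise_batch",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Noising magnitudes.  ``alpha``/``sigma_def`` are in voxels.

    Rotations default to 90-degree multiples (interpolation-free and
    label-safe); arbitrary-angle rotation exists behind ``arbitrary_angle``
    but is not the default.
    """

    elastic_alpha: float = 2.0
    elastic_sigma: float = 4.0
    gamma_range: tuple[float, float] = (0.8, 1.25)
    flip_prob: float = 0.5
    enable_elastic: bool = True
    enable_gamma: bool = True
    enable_rotate_flip: bool = True
    arbitrary_angle: bool = False

    def __post_init__(self) -> None:
        if self.elastic_alpha < 0:
            raise ValueError("elastic alpha must be >= 0")
        if self.elastic_sigma <= 0:
            raise ValueError("elastic sigma must be > 0")
        if not (0 < self.gamma_range[0] <= self.gamma_range[1]):
            raise ValueError("gamma range must be a positive interval")
        if not (0 <= self.flip_prob <= 1):
            raise ValueError("flip probability must be in [0, 1]")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def elastic_deform(roi: np.ndarray, alpha: float, sigma: float, seed) -> np.ndarray:
    """Random smooth displacement field: uniform(-1,1)^3 noise, Gaussian-smoothed
    with ``sigma`` and scaled by ``alpha`` voxels; trilinear resampling with
    mirror boundary.  ``alpha=0`` is the exact identity."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not np.all(np.isfinite(roi)):
        raise ValueError("roi contains non-finite values")
    if alpha == 0:
        return roi.copy()
    rng = _as_rng(seed)
    disp = [
        ndimage.gaussian_filter(rng.uniform(-1, 1, roi.shape), sigma) * alpha
        for _ in range(3)
    ]
    grid = np.meshgrid(*[np.arange(n, dtype=float) for n in roi.shape], indexing="ij")
    coords = [g + d for g, d in zip(grid, disp)]
    out = ndimage.map_coordinates(roi, coords, order=1, mode="reflect")
    return out.astype(roi.dtype)


def gamma_correct(roi: np.ndarray, gamma: float) -> np.ndarray:
    """Voxelwise v -> v**gamma; requires intensities in [0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if roi.min() < -1e-6 or roi.max() > 1 + 1e-6:
        raise ValueError("gamma correction requires intensities in [0, 1]")
    return np.clip(roi, 0.0, 1.0) ** gamma


def _apply_perm_flips(roi: np.ndarray, perm: tuple, flips: tuple) -> np.ndarray:
    out = np.transpose(roi, perm)
    for ax, f in enumerate(flips):
        if f:
            out = np.flip(out, axis=ax)
    return out


def rotate_flip(roi: np.ndarray, seed, flip_prob: float = 0.5, return_inverse: bool = False):
    """Random composition of axis-aligned 90-degree rotations and per-axis flips.

    Implemented as a random axis permutation plus per-axis flips — the full
    48-element cube-symmetry group — so the voxel multiset is preserved
    exactly and no interpolation occurs.  With ``return_inverse=True`` also
    returns a callable that undoes the sampled transform exactly.
    """
    if roi.ndim != 3 or len(set(roi.shape)) != 1:
        raise DimensionError(f"rotate_flip needs a cubic roi, got shape {roi.shape}")
    rng = _as_rng(seed)
    perm = tuple(rng.permutation(3))
    flips = tuple(bool(rng.random() < flip_prob) for _ in range(3))
    out = np.ascontiguousarray(_apply_perm_flips(roi, perm, flips))
    if not return_inverse:
        return out

    inv_perm = tuple(int(np.argsort(perm)[i]) for i in range(3))

    def inverse(arr: np.ndarray) -> np.ndarray:
        undone = arr
        for ax in reversed(range(3)):
            if flips[ax]:
                undone = np.flip(undone, axis=ax)
        return np.ascontiguousarray(np.transpose(undone, inv_perm))

    return out, inverse


def _rotate_arbitrary(roi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Arbitrary-angle rotation about a random coordinate plane (opt-in mode)."""
    angle = rng.uniform(0, 360)
    axes = tuple(rng.choice(3, size=2, replace=False))
    return ndimage.rotate(roi, angle, axes=axes, reshape=False, order=1, mode="reflect")


def apply_noise_batch(rois: np.ndarray, config: NoiseConfig, seeds) -> np.ndarray:
    """Batched :func:`apply_noise`: sample ``i`` equals ``apply_noise(rois[i],
    config, seeds[i])``.

    The elastic displacement fields of the whole batch are Gaussian-smoothed
    in one vectorized pass (the batch axis gets a zero-width kernel, which is
    an exact identity), which is what makes per-iteration noising cheap inside
    the training loop.
    """
    rois = np.asarray(rois, dtype=np.float32)
    b = len(rois)
    if b == 0:
        return rois.copy()
    if config.arbitrary_angle or not (
        config.enable_elastic or config.enable_gamma or config.enable_rotate_flip
    ):
        return np.stack([apply_noise(r, config, s) for r, s in zip(rois, seeds)])
    rngs = [_as_rng(s) for s in seeds]
    out = rois.copy()
    shape = rois.shape[1:]
    if config.enable_elastic and config.elastic_alpha > 0:
        u = np.empty((3, b) + shape, dtype=float)
        for i, rng in enumerate(rngs):
            for a in range(3):
                u[a, i] = rng.uniform(-1, 1, shape)
        sig = (0.0, config.elastic_sigma, config.elastic_sigma, config.elastic_sigma)
        disp = [ndimage.gaussian_filter(u[a], sig) * config.elastic_alpha for a in range(3)]
        grid = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
        for i in range(b):
            coords = [g + d[i] for g, d in zip(grid, disp)]
            out[i] = ndimage.map_coordinates(rois[i], coords, order=1, mode="reflect")
    if config.enable_gamma:
        gammas = np.asarray([rng.uniform(*config.gamma_range) for rng in rngs], dtype=np.float32)
        out = np.clip(out, 0.0, 1.0) ** gammas[:, None, None, None]
    if config.enable_rotate_flip:
        for i, rng in enumerate(rngs):
            out[i] = rotate_flip(out[i], rng, flip_prob=config.flip_prob)
    return np.clip(out, 0.0, 1.0).astype(np.float32, copy=False)


def apply_noise(roi: np.ndarray, config: NoiseConfig, seed) -> np.ndarray:
    """Seeded composition elastic -> gamma -> rotate/flip; output clipped to [0,1].

    With every transform disabled this is the identity (up to a copy).
    """
    rng = _as_rng(seed)
    out = roi
    if config.enable_elastic and config.elastic_alpha > 0:
        out = elastic_deform(out, config.elastic_alpha, config.elastic_sigma, rng)
    if config.enable_gamma:
        gamma = rng.uniform(*config.gamma_range)
        out = gamma_correct(out, gamma)
    if config.enable_rotate_flip:
        if config.arbitrary_angle:
            out = _rotate_arbitrary(out, rng)
        else:
            out = rotate_flip(out, rng, flip_prob=config.flip_prob)
    return np.clip(out, 0.0, 1.0).astype(np.float32, copy=False) if out is not roi else out.copy()
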