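"""NIfTI volume I/O, isotropic resampling and intensity normalization.

Every stage of the pipeline consumes :class:`Volume3D`: a scalar grid with
voxel spacing and a world origin, both in millimetres.  Conventions:

* voxel indices are 0-based, axes ordered (x, y, z);
* voxel *centres* map to world coordinates ``world = origin + index * spacing``;
* after :func:`resample_isotropic` the spacing is exactly (1, 1, 1) mm, which is
  the grid the candidate detector and the classifier assume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DimensionError, FormatError

log = logging.getLogger(__name__)

__all__ = [
    "Volume3D",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "normalize_intensity",
]


@dataclass
class Volume3D:
    """A 3-D scalar image in world millimetre coordinates.

    Parameters
    ----------
    data:
        Intensity grid, axes (x, y, z), float32.
    spacing:
        Voxel edge lengths in mm, strictly positive.
    origin:
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.size == 0:
            raise DimensionError(f"expected a non-empty 3-D grid, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_index(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel index of a world-mm coordinate (voxel-centre convention)."""
        return (np.asarray(xyz_mm, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def extent_mm(self) -> np.ndarray:
        """World extent spanned by voxel centres along each axis."""
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


def read_volume(path) -> Volume3D:
    """Load a NIfTI-1 volume, normalizing orientation to the closest RAS-aligned form.

    Raises ``FileNotFoundError`` for a missing path and :class:`FormatError`
    when the file is not parseable NIfTI.
    """
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
        img = nib.as_closest_canonical(img)
        data = np.asanyarray(img.dataobj, dtype=np.float32)
    except (nib.filebasedimages.ImageFileError, Exception) as exc:  # noqa: BLE001
        if isinstance(exc, FileNotFoundError):
            raise
        if not isinstance(exc, nib.filebasedimages.ImageFileError):
            # nibabel raises a mix of types on truncated/garbage input
            if isinstance(exc, (OSError, ValueError)) or "nibabel" in type(exc).__module__:
                raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
            raise
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return Volume3D(data=data, spacing=spacing, origin=origin)


def write_volume(vol: Volume3D, path) -> None:
    """Write a :class:`Volume3D` as standard NIfTI-1 (.nii / .nii.gz), float32."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine())
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def resample_isotropic(vol: Volume3D, target: float = 1.0) -> Volume3D:
    """Resample to an isotropic grid (default 1 mm³) with trilinear interpolation.

    The output grid spans the same world extent as the input within half a
    voxel; linear intensity ramps are reproduced exactly (linear functions are
    fixed points of trilinear interpolation).
    """
    if any(n < 2 for n in vol.shape):
        raise DimensionError(
            f"resampling needs >=2 voxels along every axis, got shape {vol.shape}"
        )
    spacing = np.asarray(vol.spacing)
    if np.allclose(spacing, target):
        return Volume3D(vol.data.copy(), (target,) * 3, vol.origin)
    extent = (np.asarray(vol.shape) - 1) * spacing
    # floor keeps every output voxel centre inside the input extent (no
    # extrapolation); the spanned extent shrinks by less than half a voxel
    new_shape = np.maximum(np.floor(extent / target + 1e-9).astype(int) + 1, 2)
    # new voxel centre i maps to old continuous index i * target / old_spacing
    grids = np.meshgrid(
        *[np.arange(n) * target / s for n, s in zip(new_shape, spacing)], indexing="ij"
    )
    data = ndimage.map_coordinates(
        vol.data, np.stack([g.ravel() for g in grids]), order=1, mode="nearest"
    ).reshape(tuple(new_shape))
    return Volume3D(data.astype(np.float32), (target,) * 3, vol.origin)


def normalize_intensity(vol: Volume3D, p_low: float = 1.0, p_high: float = 99.0) -> Volume3D:
    """Affine intensity map sending the ``p_low``/``p_high`` percentiles to 0/1, clipped.

    A constant input has zero percentile range; it maps to all-zeros with a
    logged warning rather than raising, since lesion-free flat phantoms are a
    legitimate degenerate case.
    """
    if not p_low < p_high:
        raise ValueError(f"need p_low < p_high, got {p_low} >= {p_high}")
    lo, hi = np.percentile(vol.data, [p_low, p_high])
    if hi <= lo:
        log.warning("constant intensity volume: normalization returns all zeros")
        return Volume3D(np.zeros_like(vol.data), vol.spacing, vol.origin)
    data = np.clip((vol.data - lo) / (hi - lo), 0.0, 1.0)
    return Volume3D(data.astype(np.float32), vol.spacing, vol.origin)
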