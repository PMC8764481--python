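"""Gray-matter volume containers, NIfTI I/O and geometric ROIs.

Volumes are modulated gray-matter density maps in a common template space
(MNI-like), carried as a 3D array plus a 4x4 voxel-to-world affine in mm.
World coordinates follow the affine exactly; no implicit axis flips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GMVolume",
    "BrainMask",
    "SphereROI",
    "load_volume",
    "save_volume",
    "load_mask",
    "make_sphere_roi",
    "roi_mean_series",
]


@dataclass
class GMVolume:
    """One subject's 3D gray-matter density map with voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Gray-matter density, unitless, finite and non-negative.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform in mm; must be invertible.
    subject_id : str
        Identifier used in error messages and manifests.
    """

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.data.ndim}D"
                + (f" (subject {self.subject_id})" if self.subject_id else "")
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("non-invertible affine")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel dimensions must be positive")

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def same_grid(self, other: "GMVolume", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class BrainMask:
    """Boolean analysis mask on the cohort grid (gray-matter voxels)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.n_voxels < 1:
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class SphereROI:
    """Closed-ball ROI: in-mask voxels whose centers lie within ``radius``
    mm of ``center_world``."""

    center_world: np.ndarray
    radius: float
    voxel_indices: np.ndarray  # (n, 3) int array
    shape: tuple = field(default=())

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    def to_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[tuple(self.voxel_indices.T)] = True
        return m


def load_volume(path, clamp_negative: bool = True, subject_id: str = "") -> GMVolume:
    """Read a 3D NIfTI gray-matter map.

    Negative densities (interpolation artifacts) are clamped to zero with a
    logged count, unless ``clamp_negative`` is False in which case they are
    rejected.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D: {path}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite values in {path}")
    n_neg = int((data < 0).sum())
    if n_neg:
        if not clamp_negative:
            raise ValueError(f"{n_neg} negative voxels in {path}")
        logger.info("clamped %d negative voxels to 0 in %s", n_neg, path)
        data = np.clip(data, 0.0, None)
    sid = subject_id or str(path)
    return GMVolume(data=data, affine=np.asarray(img.affine), subject_id=sid)


def save_volume(vol: GMVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def load_mask(path) -> BrainMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask, got {data.ndim}D: {path}")
    return BrainMask(data=data > 0, affine=np.asarray(img.affine))


def _world_grid(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """World (mm) coordinates of voxel indices ijk, shape (n, 3)."""
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def make_sphere_roi(
    center_world,
    radius: float,
    affine: np.ndarray,
    shape: tuple,
    mask: np.ndarray | None = None,
) -> SphereROI:
    """Construct a spherical seed ROI at a template coordinate.

    Membership is voxel-center-within-radius (closed ball, Euclidean
    distance in mm). The default seed of the shipped pipeline is the left
    caudate peak at MNI (-17, -3, 20) with radius 5 mm.
    """
    center_world = np.asarray(center_world, dtype=float)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    center_vox = inv[:3, :3] @ center_world + inv[:3, 3]
    if np.any(center_vox < -0.5) or np.any(center_vox > np.asarray(shape) - 0.5):
        raise ValueError(
            f"sphere center {tuple(center_world)} mm maps outside the grid"
        )
    voxel_size = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    half = np.ceil(radius / voxel_size).astype(int) + 1
    lo = np.maximum(np.floor(center_vox).astype(int) - half, 0)
    hi = np.minimum(np.ceil(center_vox).astype(int) + half + 1, shape)
    ranges = [np.arange(lo[a], hi[a]) for a in range(3)]
    ijk = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.linalg.norm(_world_grid(affine, ijk) - center_world, axis=1)
    ijk = ijk[d <= radius + 1e-9]
    if mask is not None:
        keep = np.asarray(mask, dtype=bool)[tuple(ijk.T)]
        ijk = ijk[keep]
    if len(ijk) == 0:
        raise ValueError(
            f"sphere at {tuple(center_world)} mm, radius {radius} mm has no "
            "in-mask voxels"
        )
    return SphereROI(
        center_world=center_world,
        radius=float(radius),
        voxel_indices=ijk,
        shape=tuple(shape),
    )


def roi_mean_series(volumes, roi) -> np.ndarray:
    """Mean in-ROI gray-matter density per volume, order preserved.

    ``roi`` is a :class:`SphereROI` or a boolean array on the cohort grid.
    This is the pseudo-time-series extractor once volumes are
    severity-ordered.
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("no volumes given")
    ref = volumes[0]
    if isinstance(roi, SphereROI):
        idx = tuple(roi.voxel_indices.T)
    else:
        roi = np.asarray(roi, dtype=bool)
        if not roi.any():
            raise ValueError("empty ROI")
        idx = np.nonzero(roi)
    out = np.empty(len(volumes))
    for i, v in enumerate(volumes):
        if not v.same_grid(ref):
            raise ValueError(f"grid mismatch for subject {v.subject_id}")
        out[i] = v.data[idx].mean()
    return out
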