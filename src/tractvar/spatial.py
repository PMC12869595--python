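"""Spatial variability statistics from deformation fields and bundle masks.

Two families of measures live here. Displacement statistics summarise the
subject->template warp: the per-voxel displacement magnitude, its
population mean, and the log-Jacobian determinant of the local
transformation (0 = volume preserving, <0 local compression, >0 local
expansion). Overlap statistics summarise where a bundle sits across a
population: a voxel-wise probabilistic map (percentage of subjects whose
bundle occupies the voxel) and the normalised population overlap index
(volume above a population-frequency threshold divided by the cohort-mean
bundle volume).

All grids are template-space with isotropic voxel size in mm; displacement
vectors are subject->template, stored on the template grid, in mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeGrid",
    "BinaryMask",
    "DisplacementField",
    "ProbabilisticMap",
    "displacement_magnitude",
    "log_jacobian",
    "cohort_mean_map",
    "bundle_mean_displacement",
    "mask_volume",
    "probabilistic_map",
    "overlap_index",
]


@dataclass
class VolumeGrid:
    """A 3D scalar grid in template space with isotropic voxel size (mm)."""

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid needs a 3D array, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_size) ** 3


@dataclass
class BinaryMask(VolumeGrid):
    """A {0,1} bundle mask on the template grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be 0/1, found {vals[:5]}")
        self.data = self.data.astype(bool)


@dataclass
class DisplacementField:
    """Per-voxel subject->template displacement 3-vectors, mm."""

    data: np.ndarray  # shape (nx, ny, nz, 3)
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(
                f"DisplacementField needs shape (nx,ny,nz,3), got {self.data.shape}"
            )
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")


@dataclass
class ProbabilisticMap:
    """Voxel-wise population frequency of bundle presence, 0-100 percent."""

    data: np.ndarray
    n_subjects: int
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.min() < 0 or self.data.max() > 100:
            raise ValueError("probabilistic map values must lie in [0, 100]")

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_size) ** 3


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.isfinite(arr).all():
        raise ValueError(f"{what} contains non-finite values")


def displacement_magnitude(fld: DisplacementField) -> VolumeGrid:
    """Per-voxel Euclidean norm of the displacement vector, in mm."""
    _check_finite(fld.data, "displacement field")
    mag = np.linalg.norm(fld.data, axis=-1)
    return VolumeGrid(mag, fld.voxel_size)


def log_jacobian(fld: DisplacementField) -> VolumeGrid:
    """Log-determinant of the local transformation gradient I + grad(u).

    Derivatives are taken in physical (mm) coordinates with central
    differences in the interior and one-sided differences at the grid
    boundary. Voxels where the determinant is non-positive (folding) are
    recorded as NaN and counted in a log message rather than aborting.
    """
    _check_finite(fld.data, "displacement field")
    if min(fld.data.shape[:3]) < 3:
        raise ValueError("log_jacobian needs at least 3 voxels per axis")
    h = fld.voxel_size
    # grad[i][j] = d u_i / d x_j
    grads = [np.gradient(fld.data[..., i], h, h, h) for i in range(3)]
    jac = np.empty(fld.data.shape[:3] + (3, 3))
    for i in range(3):
        for j in range(3):
            jac[..., i, j] = grads[i][j]
    jac[..., 0, 0] += 1.0
    jac[..., 1, 1] += 1.0
    jac[..., 2, 2] += 1.0
    det = np.linalg.det(jac)
    out = np.where(det > 0, np.log(np.maximum(det, np.finfo(float).tiny)), np.nan)
    n_fold = int(np.count_nonzero(~(det > 0)))
    if n_fold:
        logger.warning("log_jacobian: %d folding voxel(s) (det <= 0) set to NaN", n_fold)
    return VolumeGrid(out, fld.voxel_size)


def cohort_mean_map(maps: Sequence[VolumeGrid]) -> VolumeGrid:
    """Voxel-wise arithmetic mean of a cohort's scalar maps."""
    if len(maps) == 0:
        raise ValueError("cohort_mean_map needs at least one map")
    shape = maps[0].data.shape
    vs = maps[0].voxel_size
    for m in maps[1:]:
        if m.data.shape != shape or m.voxel_size != vs:
            raise ValueError("all maps must share the same grid and voxel size")
    stack = np.stack([m.data for m in maps])
    return VolumeGrid(stack.mean(axis=0), vs)


def bundle_mean_displacement(disp_map: VolumeGrid, mask: BinaryMask) -> float:
    """Mean of a displacement-magnitude map over a bundle mask, mm."""
    if disp_map.data.shape != mask.data.shape:
        raise ValueError("map and mask grids differ")
    if not mask.data.any():
        raise ValueError("bundle mask is empty; mean displacement undefined")
    return float(disp_map.data[mask.data].mean())


def mask_volume(mask: BinaryMask) -> float:
    """Mask volume in mm^3 (voxel count x voxel volume)."""
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume


def probabilistic_map(masks: Sequence[BinaryMask]) -> ProbabilisticMap:
    """Voxel-wise percentage of subjects whose bundle occupies the voxel."""
    if len(masks) < 2:
        raise ValueError("probabilistic_map needs at least two subjects")
    shape = masks[0].data.shape
    vs = masks[0].voxel_size
    for m in masks[1:]:
        if m.data.shape != shape or m.voxel_size != vs:
            raise ValueError("all masks must share the same grid and voxel size")
    counts = np.zeros(shape, dtype=np.int64)
    for m in masks:
        counts += m.data
    freq = 100.0 * counts / len(masks)
    return ProbabilisticMap(freq, n_subjects=len(masks), voxel_size=vs)


def overlap_index(pmap: ProbabilisticMap, threshold: float, mean_volume: float) -> float:
    """Normalised population overlap at a population-frequency threshold.

    Volume of the region where at least ``threshold`` percent of subjects
    carry the bundle, divided by the cohort-mean bundle volume (mm^3,
    template space). May exceed 1 at permissive thresholds. Voxels are
    counted with >= so that a core shared by the entire population counts
    at every threshold level.
    """
    if not (0 < threshold <= 100):
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    if not mean_volume > 0:
        raise ValueError(f"mean_volume must be positive, got {mean_volume}")
    n_above = int(np.count_nonzero(pmap.data >= threshold))
    return n_above * pmap.voxel_volume / mean_volume
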