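"""Masking, log-transform and subject residual profiles for SUVr volumes.

The SSM preprocessing chain: per-subject masks keep voxels at or above a
fraction (default 3%) of that subject's maximum uptake; the common mask is
their intersection; masked uptake is natural-log transformed; the
control-group voxelwise mean of the log images (the group mean profile) is
subtracted from every subject, yielding subject residual profiles (SRP).
No further within-subject or across-subject demeaning is applied.

Vectorization is deterministic row-major (C order) over the grid, identical
for every subject in a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class SuvrVolume:
    """One subject's 3-D parametric SUVr image on a shared voxel grid."""

    subject_id: str
    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"{self.subject_id}: expected 3-D volume, got {self.data.ndim}-D"
            )

    @classmethod
    def from_nifti(cls, path: str | Path, subject_id: str | None = None) -> "SuvrVolume":
        img = nib.load(str(path))
        sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
        return cls(sid, np.asanyarray(img.dataobj, dtype=float), img.affine)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


@dataclass
class VoxelMask:
    """Boolean grid plus the row-major index list of included voxels."""

    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def indices(self) -> np.ndarray:
        """Flat C-order indices of masked voxels (deterministic ordering)."""
        return np.flatnonzero(self.mask.ravel(order="C"))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def vectorize(self, volume: np.ndarray) -> np.ndarray:
        """Extract masked voxel values as a vector, row-major order."""
        volume = np.asarray(volume)
        if volume.shape != self.mask.shape:
            raise ValueError(f"shape mismatch: {volume.shape} vs {self.mask.shape}")
        return volume.ravel(order="C")[self.indices]

    def unvectorize(self, vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place a masked-voxel vector back onto the full grid."""
        vec = np.asarray(vec)
        if vec.shape != (self.n_voxels,):
            raise ValueError(f"expected vector of length {self.n_voxels}, got {vec.shape}")
        out = np.full(self.mask.size, fill, dtype=float)
        out[self.indices] = vec
        return out.reshape(self.mask.shape, order="C")

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VoxelMask":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj) > 0, img.affine)


@dataclass
class GroupMeanProfile:
    """Voxelwise mean of reference-group log-uptake within the common mask."""

    values: np.ndarray
    reference_ids: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.reference_ids = tuple(self.reference_ids)


@dataclass
class SrpMatrix:
    """Subjects x masked-voxels matrix of log-uptake deviations."""

    matrix: np.ndarray
    subject_ids: tuple
    mask: VoxelMask
    profile: GroupMeanProfile

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.subject_ids = tuple(self.subject_ids)
        if self.matrix.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match subject list")

    def row(self, subject_id) -> np.ndarray:
        return self.matrix[self.subject_ids.index(subject_id)]


def _check_same_grid(items: Sequence, what: str) -> None:
    shapes = {x.data.shape if hasattr(x, "data") else x.mask.shape for x in items}
    if len(shapes) > 1:
        raise ValueError(f"{what} not on a common grid: shapes {sorted(shapes)}")
    first = items[0].affine
    for x in items[1:]:
        if not np.allclose(x.affine, first, atol=1e-6):
            raise ValueError(f"{what} have differing voxel-to-world transforms")


def build_subject_mask(vol: SuvrVolume, fraction: float = 0.03) -> VoxelMask:
    """Mask of voxels with uptake >= ``fraction`` of the subject's maximum.

    The threshold is inclusive.  Errors if the volume has a non-positive or
    non-finite maximum (no definable threshold).
    """
    if not np.all(np.isfinite(vol.data)):
        raise ValueError(f"{vol.subject_id}: volume contains non-finite values")
    vmax = float(vol.data.max())
    if vmax <= 0:
        raise ValueError(f"{vol.subject_id}: non-positive maximum uptake ({vmax})")
    return VoxelMask(vol.data >= fraction * vmax, vol.affine)


def build_common_mask(masks: Sequence[VoxelMask]) -> VoxelMask:
    """Voxelwise intersection of per-subject masks; errors if empty."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    _check_same_grid(masks, "masks")
    common = np.logical_and.reduce([m.mask for m in masks])
    if not common.any():
        raise ValueError("common mask is empty (no voxel present in every subject)")
    return VoxelMask(common, masks[0].affine)


def extract_log_matrix(
    vols: Sequence[SuvrVolume], mask: VoxelMask
) -> tuple[np.ndarray, tuple]:
    """Natural log of masked uptake, one row per subject.

    Errors (naming subject and voxel) on any non-positive masked value:
    training-time inputs must be log-definable, no silent clamping.
    Returns (matrix, subject_ids).
    """
    if len(vols) == 0:
        raise ValueError("need at least one volume")
    _check_same_grid(list(vols) + [mask], "volumes/mask")
    rows = []
    for vol in vols:
        vec = mask.vectorize(vol.data)
        bad = np.flatnonzero(vec <= 0)
        if bad.size:
            flat_idx = int(mask.indices[bad[0]])
            voxel = np.unravel_index(flat_idx, mask.mask.shape)
            raise ValueError(
                f"subject '{vol.subject_id}': non-positive uptake at masked voxel "
                f"{tuple(int(v) for v in voxel)} (value {vec[bad[0]]:g})"
            )
        rows.append(np.log(vec))
    return np.vstack(rows), tuple(v.subject_id for v in vols)


def group_mean_profile(
    logmat: np.ndarray, subject_ids: Sequence, reference_ids: Iterable
) -> GroupMeanProfile:
    """Voxelwise mean of reference-group rows of the log matrix."""
    subject_ids = list(subject_ids)
    reference_ids = [s for s in subject_ids if s in set(reference_ids)]
    if not reference_ids:
        raise ValueError("empty reference set")
    idx = [subject_ids.index(s) for s in reference_ids]
    return GroupMeanProfile(np.asarray(logmat)[idx].mean(axis=0), reference_ids)


def compute_srp(
    logmat: np.ndarray,
    subject_ids: Sequence,
    profile: GroupMeanProfile,
    mask: VoxelMask,
) -> SrpMatrix:
    """Subtract the group mean profile from every row; nothing else.

    No within-subject or across-subject demeaning beyond the profile
    subtraction (intensity normalization already happened in SUVr space).
    """
    logmat = np.asarray(logmat, dtype=float)
    if logmat.shape[1] != profile.values.shape[0]:
        raise ValueError(
            f"profile length {profile.values.shape[0]} does not match "
            f"matrix columns {logmat.shape[1]}"
        )
    return SrpMatrix(logmat - profile.values, tuple(subject_ids), mask, profile)


def prepare_srp(
    vols: Sequence[SuvrVolume],
    reference_ids: Iterable,
    mask_fraction: float = 0.03,
) -> SrpMatrix:
    """Full chain: subject masks -> common mask -> log -> profile -> SRP."""
    masks = [build_subject_mask(v, mask_fraction) for v in vols]
    common = build_common_mask(masks)
    logmat, ids = extract_log_matrix(vols, common)
    profile = group_mean_profile(logmat, ids, reference_ids)
    return compute_srp(logmat, ids, profile, common)
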