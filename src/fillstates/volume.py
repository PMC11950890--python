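"""In-memory containers for template-space volumes and binary masks.

All volumes handled by this package are assumed to live on a common
template grid already (spatial normalization happens upstream); the only
geometric operation supported is an exact alignment check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Elementwise tolerance for declaring two affines equal.
AFFINE_TOL = 1e-4

MODALITIES = ("amyloid", "tau", "neurodegeneration", "raw")


class AlignmentError(ValueError):
    """Two grids do not share shape and affine."""


class NormalizationError(ValueError):
    """Reference-region mean is non-positive or non-finite."""


class EmptyROIError(ValueError):
    """A mask contains no usable voxels."""


@dataclass
class VolumeGrid:
    """A 3D scalar image on a fixed grid.

    Parameters
    ----------
    values : ndarray, shape (i, j, k)
        Voxel intensities (tracer uptake, SUVR, or z-scores). Non-finite
        entries are treated as missing by downstream marker computations.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform.
    modality : str
        One of ``amyloid``, ``tau``, ``neurodegeneration`` or ``raw``.
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(f"expected a non-empty 3D array, got shape {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def aligned_with(self, other: "VolumeGrid | MaskVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_TOL, rtol=0.0
        )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass
class MaskVolume:
    """A binary region mask on the same grid convention as :class:`VolumeGrid`."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        # binarize at > 0.5 so probabilistic atlas masks load sanely
        self.values = (vals > 0.5).astype(np.uint8) if vals.dtype.kind == "f" else (
            vals != 0
        ).astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.values.sum() == 0:
            raise EmptyROIError(f"mask {self.label!r} has no voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def aligned_with(self, other) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_TOL, rtol=0.0
        )

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.uint8), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


def load_volume(path, modality: str = "raw") -> VolumeGrid:
    """Load a NIfTI volume as a :class:`VolumeGrid`."""
    img = nib.load(str(path))
    return VolumeGrid(np.asarray(img.dataobj, dtype=float), img.affine, modality)


def load_mask(path, label: str = "") -> MaskVolume:
    """Load a NIfTI mask, binarizing at > 0.5."""
    img = nib.load(str(path))
    return MaskVolume(np.asarray(img.dataobj, dtype=float), img.affine, label or str(path))


def require_aligned(a, b, what: str = "grids") -> None:
    if not a.aligned_with(b):
        raise AlignmentError(
            f"misaligned {what}: shapes {a.shape} vs {b.shape} or affines differ "
            f"beyond tolerance {AFFINE_TOL}"
        )
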