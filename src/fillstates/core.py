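"""Fill-state, SUVR and abnormal-intensity markers from template-space PET.

The pipeline: divide a raw uptake map by its reference-region mean (SUVR),
z-standardize against the voxelwise mean/SD of an amyloid-negative
cognitively normal control cohort, threshold |z| at a one-tailed cutoff
(default 1.65, P < .05) in the pathologic direction, and summarize a
meta-ROI by

* fill state   — percentage of ROI voxels classified abnormal (extent),
* SUVR         — mean intensity over the ROI (quantity),
* abnormal-voxel intensity — mean z of only the abnormal voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volume import (
    EmptyROIError,
    MaskVolume,
    NormalizationError,
    VolumeGrid,
    require_aligned,
)

logger = logging.getLogger(__name__)

#: One-tailed standard-normal 5% quantile, rounded to two decimals: the
#: default voxel abnormality cutoff.
DEFAULT_CUTOFF = 1.65

#: Control SD below this (SUVR units) is clamped to avoid unbounded z.
SD_FLOOR = 1e-6

#: Pathologic direction per modality: tracer-binding pathologies are
#: hyper-signals, neurodegeneration (hypometabolism/perfusion) is a hypo-signal.
DEFAULT_DIRECTIONS = {"amyloid": "greater", "tau": "greater", "neurodegeneration": "less"}

#: Per-modality default cutoff: the sign follows the pathologic direction.
DEFAULT_CUTOFFS = {"amyloid": 1.65, "tau": 1.65, "neurodegeneration": -1.65}


class ModalityError(ValueError):
    """Subject and control model carry different modalities."""


class InsufficientSampleError(ValueError):
    """Fewer than two control volumes supplied."""


@dataclass
class ControlModel:
    """Voxelwise normative model: sample mean and SD over control subjects."""

    mean_map: np.ndarray
    sd_map: np.ndarray
    n_controls: int
    modality: str
    affine: np.ndarray
    sd_floor: float = SD_FLOOR

    def __post_init__(self) -> None:
        if self.mean_map.shape != self.sd_map.shape:
            raise ValueError("mean_map and sd_map shapes differ")
        if self.n_controls < 2:
            raise InsufficientSampleError("control model needs n >= 2")

    @property
    def shape(self):
        return self.mean_map.shape

    def aligned_with(self, other) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-4, rtol=0.0
        )

    @property
    def n_floored_voxels(self) -> int:
        return int((self.sd_map < self.sd_floor).sum())


@dataclass
class AbnormalityMap:
    """Binary voxel classification against a z cutoff inside an ROI."""

    values: np.ndarray  # uint8, 1 = abnormal
    cutoff: float
    direction: str
    affine: np.ndarray

    @property
    def n_abnormal(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self):
        return self.values.shape

    def aligned_with(self, other) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-4, rtol=0.0
        )


@dataclass
class MarkerSet:
    """Per-subject, per-modality markers for one meta-ROI.

    ``abnormal_intensity`` is ``None`` (undefined, not zero) when no voxel
    is abnormal; by construction it is defined iff ``fill_state > 0``.
    """

    fill_state: float
    suvr: float
    abnormal_intensity: float | None
    modality: str
    roi_label: str
    cutoff: float = DEFAULT_CUTOFF
    direction: str = "greater"
    n_roi_voxels: int = 0
    n_abnormal_voxels: int = 0


def intensity_normalize(raw: VolumeGrid, reference: MaskVolume) -> VolumeGrid:
    """Divide a raw uptake map by its mean over the reference region (SUVR).

    The output mean over the reference mask is 1 by construction.
    """
    require_aligned(raw, reference, "volume and reference mask")
    ref_vals = raw.values[reference.as_bool()]
    ref_vals = ref_vals[np.isfinite(ref_vals)]
    if ref_vals.size == 0:
        raise NormalizationError("reference region has no finite voxels")
    ref_mean = float(ref_vals.mean())
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise NormalizationError(f"reference mean {ref_mean} is not positive")
    return VolumeGrid(raw.values / ref_mean, raw.affine, raw.modality)


def fit_control_model(controls: Sequence[VolumeGrid], modality: str) -> ControlModel:
    """Voxelwise sample mean and SD (ddof=1) over aligned control SUVR maps."""
    if len(controls) < 2:
        raise InsufficientSampleError(f"need >= 2 controls, got {len(controls)}")
    first = controls[0]
    for c in controls[1:]:
        require_aligned(first, c, "control volumes")
    stack = np.stack([c.values for c in controls])
    mean_map = stack.mean(axis=0)
    sd_map = stack.std(axis=0, ddof=1)
    model = ControlModel(mean_map, sd_map, len(controls), modality, first.affine.copy())
    if model.n_floored_voxels:
        logger.info(
            "control model (%s): %d voxels with SD < %g clamped",
            modality, model.n_floored_voxels, model.sd_floor,
        )
    return model


def z_standardize(subject: VolumeGrid, model: ControlModel) -> VolumeGrid:
    """z(v) = (subject(v) - mean(v)) / max(sd(v), sd_floor)."""
    if subject.modality != model.modality:
        raise ModalityError(
            f"subject modality {subject.modality!r} != model modality {model.modality!r}"
        )
    require_aligned(subject, model, "subject and control model")
    sd = np.maximum(model.sd_map, model.sd_floor)
    return VolumeGrid((subject.values - model.mean_map) / sd, subject.affine, subject.modality)


def classify_voxels(
    zmap: VolumeGrid,
    roi: MaskVolume,
    cutoff: float = DEFAULT_CUTOFF,
    direction: str = "greater",
) -> AbnormalityMap:
    """Flag ROI voxels beyond the cutoff (strict inequality; ties negative).

    Non-finite z values never classify as abnormal.
    """
    require_aligned(zmap, roi, "z-map and ROI")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    z = zmap.values
    with np.errstate(invalid="ignore"):
        beyond = z > cutoff if direction == "greater" else z < cutoff
    beyond &= np.isfinite(z)
    ab = (beyond & roi.as_bool()).astype(np.uint8)
    return AbnormalityMap(ab, float(cutoff), direction, zmap.affine.copy())


def _usable_roi(values: np.ndarray, roi: MaskVolume) -> np.ndarray:
    """ROI restricted to finite voxels; missing voxels are logged and dropped
    from both numerator and denominator."""
    mask = roi.as_bool()
    finite = np.isfinite(values)
    n_missing = int((mask & ~finite).sum())
    if n_missing:
        logger.info("ROI %r: excluded %d non-finite voxels", roi.label, n_missing)
    return mask & finite


def fill_state(ab: AbnormalityMap, roi: MaskVolume, zmap: VolumeGrid | None = None) -> float:
    """Percentage of ROI voxels classified abnormal, in [0, 100].

    If the source z-map is given, its non-finite voxels are excluded from
    the denominator (they can never be abnormal).
    """
    require_aligned(ab, roi, "abnormality map and ROI")
    usable = _usable_roi(zmap.values, roi) if zmap is not None else roi.as_bool()
    denom = int(usable.sum())
    if denom == 0:
        raise EmptyROIError("ROI has no usable voxels")
    return 100.0 * float(ab.values[usable].sum()) / denom


def roi_suvr(suvr: VolumeGrid, roi: MaskVolume) -> float:
    """Arithmetic mean intensity over the (finite) ROI voxels."""
    require_aligned(suvr, roi, "SUVR map and ROI")
    usable = _usable_roi(suvr.values, roi)
    if not usable.any():
        raise EmptyROIError("ROI has no usable voxels")
    return float(suvr.values[usable].mean())


def abnormal_intensity(zmap: VolumeGrid, ab: AbnormalityMap) -> float | None:
    """Mean z over abnormal voxels; ``None`` when no voxel is abnormal."""
    require_aligned(zmap, ab, "z-map and abnormality map")
    sel = ab.values.astype(bool)
    if not sel.any():
        return None
    return float(zmap.values[sel].mean())


def compute_markers(
    subject: VolumeGrid,
    model: ControlModel,
    roi: MaskVolume,
    cutoff: float = DEFAULT_CUTOFF,
    direction: str = "greater",
) -> MarkerSet:
    """Full marker derivation for one subject: z-map, classification, summary."""
    zmap = z_standardize(subject, model)
    ab = classify_voxels(zmap, roi, cutoff, direction)
    fs = fill_state(ab, roi, zmap=zmap)
    return MarkerSet(
        fill_state=fs,
        suvr=roi_suvr(subject, roi),
        abnormal_intensity=abnormal_intensity(zmap, ab),
        modality=subject.modality,
        roi_label=roi.label,
        cutoff=float(cutoff),
        direction=direction,
        n_roi_voxels=int(_usable_roi(zmap.values, roi).sum()),
        n_abnormal_voxels=ab.n_abnormal,
    )
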