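"""Seedable synthetic phantom cohorts with known ground-truth lesion extent.

A phantom cohort consists of a smooth voxelwise normative field (mean in
[1.0, 1.4] SUVR, SD in [0.05, 0.15]), control volumes drawn from it, and
patient volumes carrying a contiguous lesion of a requested fractional
extent inside a centered ellipsoidal meta-ROI. Amyloid- and tau-like
lesions shift intensity up, neurodegeneration-like lesions shift it down,
each by a fixed multiple of the local control SD. Diagnostic groups carry
increasing expected extent (CN < SCD < MCI < dementia) and cognitive
scores decline linearly in true extent with age/sex/education covariates
plus Gaussian noise.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .core import DEFAULT_DIRECTIONS
from .volume import MaskVolume, VolumeGrid

GROUPS = ("CN", "SCD", "MCI", "dementia")


class ConfigError(ValueError):
    pass


@dataclass
class PhantomConfig:
    """Geometry and population parameters of a phantom cohort.

    The meta-ROI is a centered ellipsoid (~28% of the default 32x32x32
    grid); the reference region is a disjoint slab at the bottom of the
    grid; a gray-matter mask is a larger ellipsoid containing the ROI.
    """

    shape: tuple = (32, 32, 32)
    roi_semi_axes: tuple = (14.0, 13.0, 12.0)
    reference_slab_thickness: int = 3
    gm_semi_axes: tuple = (15.5, 15.0, 13.5)
    mu_range: tuple = (1.0, 1.4)
    sigma_range: tuple = (0.05, 0.15)
    field_smoothness: float = 4.0  # voxels, smoothing of the mu/sigma fields
    n_controls: int = 40
    group_fractions: dict = field(
        default_factory=lambda: {"CN": 0.02, "SCD": 0.10, "MCI": 0.30, "dementia": 0.55}
    )
    fraction_jitter: float = 0.05
    effect_size: float = 5.0  # lesion shift in local-SD units
    directions: dict = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    noise_smoothing: float = 0.0  # 0 = voxelwise-independent noise
    lesion_mode: str = "contiguous"  # or "scattered"
    amyloid_negative_max_f: float = 0.05
    seed: int = 0

    def rng(self, *stream) -> np.random.Generator:
        """Deterministic generator for a named sub-stream of this config."""
        return np.random.default_rng([self.seed & 0x7FFFFFFF, *stream])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d


def _ellipsoid(shape, semi_axes) -> np.ndarray:
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def make_masks(config: PhantomConfig) -> tuple[MaskVolume, MaskVolume, MaskVolume]:
    """Deterministic (roi, reference, graymatter) masks for a config."""
    roi = _ellipsoid(config.shape, config.roi_semi_axes)
    ref = np.zeros(config.shape, dtype=bool)
    ref[:, :, : config.reference_slab_thickness] = True
    gm = _ellipsoid(config.shape, config.gm_semi_axes) & ~ref
    if (roi & ref).any():
        raise ConfigError("ROI and reference region overlap; shrink the ROI or the slab")
    if not (roi <= gm).all():
        raise ConfigError("gray-matter mask must contain the ROI")
    affine = np.eye(4)
    return (
        MaskVolume(roi, affine, "meta-ROI"),
        MaskVolume(ref, affine, "reference slab"),
        MaskVolume(gm, affine, "gray matter"),
    )


def _smooth_field(config: PhantomConfig, stream: int, lo: float, hi: float) -> np.ndarray:
    rng = config.rng(stream)
    raw = ndimage.gaussian_filter(rng.standard_normal(config.shape), config.field_smoothness)
    span = raw.max() - raw.min()
    return lo + (hi - lo) * (raw - raw.min()) / span


def mu_field(config: PhantomConfig) -> np.ndarray:
    """Smooth normative mean SUVR field, deterministic per config."""
    return _smooth_field(config, 101, *config.mu_range)


def sigma_field(config: PhantomConfig) -> np.ndarray:
    """Smooth normative SD field, deterministic per config."""
    return _smooth_field(config, 102, *config.sigma_range)


def _noise(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(config.shape)
    if config.noise_smoothing > 0:
        eps = ndimage.gaussian_filter(eps, config.noise_smoothing)
        eps /= eps.std()  # restore unit scale; spatial correlation remains
    return eps


def generate_control(config: PhantomConfig, seed: int, modality: str = "tau") -> VolumeGrid:
    """One control volume: voxelwise Normal(mu(v), sigma(v))."""
    rng = config.rng(1, seed)
    vol = mu_field(config) + sigma_field(config) * _noise(config, rng)
    return VolumeGrid(vol, np.eye(4), modality)


def _grow_lesion(roi: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous lesion of n voxels grown by BFS from a random ROI voxel."""
    idx = np.argwhere(roi)
    start = tuple(idx[rng.integers(len(idx))])
    shape = roi.shape
    seen = {start}
    order = [start]
    queue = deque([start])
    offsets = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
    while queue and len(order) < n:
        x, y, z = queue.popleft()
        for dx, dy, dz in offsets:
            v = (x + dx, y + dy, z + dz)
            if (
                0 <= v[0] < shape[0] and 0 <= v[1] < shape[1] and 0 <= v[2] < shape[2]
                and v not in seen and roi[v]
            ):
                seen.add(v)
                order.append(v)
                queue.append(v)
                if len(order) >= n:
                    break
    lesion = np.zeros(shape, dtype=bool)
    for v in order[:n]:
        lesion[v] = True
    return lesion


def generate_patient(
    config: PhantomConfig, f: float, seed: int, modality: str = "tau"
) -> tuple[VolumeGrid, float]:
    """Patient volume with a lesion covering fraction ``f`` of the ROI.

    The background shares the control generator path, so ``f = 0`` is
    statistically a control. Lesion voxels are shifted by
    ``effect_size * sigma(v)`` in the modality's pathologic direction.
    Returns the volume and the exactly realized fraction.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"lesion fraction must be in [0, 1], got {f}")
    rng = config.rng(1, seed)
    sigma = sigma_field(config)
    vol = mu_field(config) + sigma * _noise(config, rng)

    roi, _, _ = make_masks(config)
    n_roi = roi.n_voxels
    n_lesion = int(round(f * n_roi))
    realized = n_lesion / n_roi
    if n_lesion > 0:
        if config.lesion_mode == "contiguous":
            lesion = _grow_lesion(roi.as_bool(), n_lesion, rng)
        elif config.lesion_mode == "scattered":
            idx = np.argwhere(roi.as_bool())
            pick = idx[rng.choice(len(idx), size=n_lesion, replace=False)]
            lesion = np.zeros(config.shape, dtype=bool)
            lesion[tuple(pick.T)] = True
        else:
            raise ConfigError(f"unknown lesion_mode {config.lesion_mode!r}")
        sign = 1.0 if config.directions.get(modality, "greater") == "greater" else -1.0
        vol = vol + sign * config.effect_size * sigma * lesion
    return VolumeGrid(vol, np.eye(4), modality), realized


@dataclass
class CognitionModel:
    """Linear generators for three cognitive scores (global, memory, executive).

    score = intercept + load_f * f + load_age * (age - 70) + load_sex * sex
            + load_edu * (education - 14) + Normal(0, noise_sd).
    All loadings on the true lesion fraction f are negative: more extent,
    worse cognition.
    """

    intercepts: tuple = (29.0, 0.8, 0.6)
    f_loadings: tuple = (-12.0, -2.5, -2.0)
    age_loadings: tuple = (-0.05, -0.012, -0.012)
    sex_loadings: tuple = (0.2, 0.05, 0.0)
    edu_loadings: tuple = (0.08, 0.02, 0.02)
    noise_sd: tuple = (1.2, 0.4, 0.4)
    score_names: tuple = ("score_global", "score_memory", "score_executive")

    def __post_init__(self) -> None:
        if not all(l < 0 for l in self.f_loadings):
            raise ConfigError("all lesion-fraction loadings must be negative")
        if not all(s > 0 for s in self.noise_sd):
            raise ConfigError("noise SDs must be positive")

    def sample(self, f, age, sex, education, rng) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        out = []
        for i in range(3):
            mu = (
                self.intercepts[i]
                + self.f_loadings[i] * f
                + self.age_loadings[i] * (np.asarray(age) - 70.0)
                + self.sex_loadings[i] * np.asarray(sex)
                + self.edu_loadings[i] * (np.asarray(education) - 14.0)
            )
            out.append(mu + self.noise_sd[i] * rng.standard_normal(f.shape))
        return np.column_stack(out)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    config: PhantomConfig,
    cognition: CognitionModel | None = None,
    group_sizes: dict | None = None,
    outdir: str | Path | None = None,
    modalities: tuple = ("amyloid", "tau", "neurodegeneration"),
) -> tuple[dict, pd.DataFrame]:
    """Full phantom cohort: per-subject volumes plus a covariate table.

    Each subject gets one volume per modality, all driven by the same true
    lesion fraction (pathology axes co-progress in the phantom). Ages are
    Normal(70, 7) truncated to [50, 90], education Normal(14, 3) truncated
    to [8, 22], sex Bernoulli(0.5). When ``outdir`` is given, volumes,
    masks, cohort.csv and a JSON manifest are written there; volumes are
    always also returned in memory as {(subject_id, modality): VolumeGrid}.
    """
    cognition = cognition or CognitionModel()
    group_sizes = group_sizes or {"CN": 30, "SCD": 30, "MCI": 30, "dementia": 30}
    if any(n <= 0 for n in group_sizes.values()):
        raise ConfigError("group sizes must be positive")
    rng = config.rng(2)

    rows = []
    volumes: dict[tuple[str, str], VolumeGrid] = {}
    subj_counter = 0
    for group in GROUPS:
        n = group_sizes.get(group, 0)
        if n == 0:
            continue
        f_mean = config.group_fractions[group]
        fs = np.clip(
            rng.normal(f_mean, config.fraction_jitter, size=n), 0.0, 1.0
        )
        ages = _truncated_normal(rng, 70.0, 7.0, 50.0, 90.0, n)
        edus = _truncated_normal(rng, 14.0, 3.0, 8.0, 22.0, n)
        sexes = rng.integers(0, 2, size=n)
        scores = cognition.sample(fs, ages, sexes, edus, rng)
        for i in range(n):
            sid = f"sub-{subj_counter:04d}"
            subj_counter += 1
            realized = {}
            for m_idx, modality in enumerate(modalities):
                vol, real_f = generate_patient(
                    config, float(fs[i]), seed=subj_counter * 8 + m_idx, modality=modality
                )
                volumes[(sid, modality)] = vol
                realized[modality] = real_f
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": float(ages[i]),
                    "sex": int(sexes[i]),
                    "education": float(edus[i]),
                    "score_global": float(scores[i, 0]),
                    "score_memory": float(scores[i, 1]),
                    "score_executive": float(scores[i, 2]),
                    "true_f": float(realized.get(modalities[0], fs[i])),
                    "amyloid_status": (
                        "negative" if fs[i] < config.amyloid_negative_max_f else "positive"
                    ),
                }
            )
    cohort = pd.DataFrame(rows)

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "volumes").mkdir(parents=True, exist_ok=True)
        (outdir / "masks").mkdir(exist_ok=True)
        roi, ref, gm = make_masks(config)
        roi.save(outdir / "masks" / "meta_roi.nii.gz")
        ref.save(outdir / "masks" / "reference.nii.gz")
        gm.save(outdir / "masks" / "graymatter.nii.gz")
        for (sid, modality), vol in volumes.items():
            vol.save(outdir / "volumes" / f"{sid}_{modality}.nii.gz")
        cohort.to_csv(outdir / "cohort.csv", index=False)
        manifest = {
            "config": config.to_dict(),
            "group_sizes": group_sizes,
            "modalities": list(modalities),
            "n_subjects": len(cohort),
            "n_volumes": len(volumes),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return volumes, cohort
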