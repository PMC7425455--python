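"""Seeded synthetic cohorts and smooth GMV-like volumes with known structure.

The generator produces a four-group cohort with six binary risk factors,
cognitive scores wired through an explicit mediation chain, and per-subject
3D gray-matter-like images in which risk burden removes volume from known
regions of interest.  Every quantity downstream stages try to estimate
(slopes ``a``, ``b``, the indirect effect ``a*b``, ROI locations, noise
smoothness) is therefore available as ground truth.

Generative model (additive linear Gaussian):

* composite score ``X``: sum of six Bernoulli factors with group-dependent
  prevalence;
* true mediator ``M`` (mean GMV over the ROI union):
  ``M = template_roi_mean + beta_vrf_gmv * X + eps_med``;
* cognition ``Y``: ``Y = baseline + beta_gmv_cog * (M - template_roi_mean)
  + beta_direct * X + eps_cog`` (MMSE clipped to [0, 30]);
* images: smooth template + additive group atrophy outside the ROIs +
  ``(M - template_roi_mean)`` inside each ROI + Gaussian noise smoothed to
  ``smoothing_fwhm_mm`` and rescaled to voxel SD ``noise_sd_image``.

The implied true indirect effect per outcome is
``beta_vrf_gmv * beta_gmv_cog`` and is recorded, not re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import rng_for
from .images import VolumeImage, smooth_gaussian
from .scoring import FACTORS

__all__ = [
    "GroundTruth",
    "SyntheticImages",
    "generate_cohort",
    "generate_gmv_images",
    "make_mediation_dataset",
]

DEFAULT_GROUPS = ("CN", "EMCI", "LMCI", "AD")
DEFAULT_GROUP_SIZES = (69, 52, 41, 30)

# Per-group factor prevalences, ordered as scoring.FACTORS.  Row sums give
# unit-weight composite-score means of 1.10 / 1.40 / 1.40 / 2.10.
DEFAULT_VRF_PREVALENCE = (
    (0.25, 0.45, 0.05, 0.10, 0.15, 0.10),
    (0.30, 0.55, 0.07, 0.15, 0.18, 0.15),
    (0.32, 0.52, 0.08, 0.16, 0.17, 0.15),
    (0.45, 0.70, 0.15, 0.25, 0.30, 0.25),
)

# demographic draw parameters per group
_AGE_MEAN = (73.6, 71.2, 71.5, 73.1)
_AGE_SD = (5.9, 6.7, 8.1, 6.8)
_FEMALE_P = (40 / 69, 31 / 52, 17 / 41, 15 / 30)
_APOE_P = (21 / 69, 26 / 52, 17 / 41, 22 / 30)

DEFAULT_ROI_SPECS = (
    ("ROI_A", (0.38, 0.42, 0.50), 3.0),
    ("ROI_B", (0.62, 0.58, 0.50), 3.0),
)


def _sphere(shape: tuple[int, int, int], center_vox: np.ndarray, radius_vox: float) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center_vox))
    return dist2 <= radius_vox**2


@dataclass
class GroundTruth:
    """Full parameterization of one synthetic dataset."""

    group_names: tuple[str, ...] = DEFAULT_GROUPS
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    vrf_prevalence: tuple[tuple[float, ...], ...] = DEFAULT_VRF_PREVALENCE
    beta_vrf_gmv: float = -0.03
    beta_gmv_cog: dict[str, float] = field(
        default_factory=lambda: {"mmse": 40.0, "adascog": -80.0}
    )
    beta_direct: dict[str, float] = field(
        default_factory=lambda: {"mmse": -0.3, "adascog": 0.8}
    )
    noise_sd_image: float = 0.02
    noise_sd_mediator: float = 0.05
    noise_sd_cog: dict[str, float] = field(
        default_factory=lambda: {"mmse": 1.0, "adascog": 3.0}
    )
    smoothing_fwhm_mm: float = 6.0
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    roi_specs: tuple[tuple[str, tuple[float, float, float], float], ...] = DEFAULT_ROI_SPECS
    group_atrophy: tuple[float, ...] = (0.0, -0.004, -0.008, -0.015)
    mmse_baseline: float = 25.0
    adascog_baseline: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.group_names)
        if len(self.group_sizes) != k or len(self.group_atrophy) != k:
            raise ValueError("group_sizes and group_atrophy must match group_names")
        if any(int(n) < 2 for n in self.group_sizes):
            raise ValueError("all group sizes must be >= 2")
        prev = np.asarray(self.vrf_prevalence, dtype=float)
        if prev.shape != (k, len(FACTORS)):
            raise ValueError(
                f"vrf_prevalence must have shape ({k}, {len(FACTORS)}), got {prev.shape}"
            )
        if np.any((prev < 0) | (prev > 1)):
            raise ValueError("prevalences must lie in [0, 1]")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")
        for sd in (self.noise_sd_image, self.noise_sd_mediator, *self.noise_sd_cog.values()):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")

    # ------------------------------------------------------------------ geometry

    def brain_mask(self) -> np.ndarray:
        """Ellipsoidal brain mask with semi-axes 0.42 x grid extent."""
        shape = self.grid_shape
        grids = np.indices(shape, dtype=float)
        center = [(s - 1) / 2.0 for s in shape]
        semi = [0.42 * s for s in shape]
        dist2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
        return dist2 <= 1.0

    def roi_masks(self) -> dict[str, np.ndarray]:
        """Labeled, disjoint spherical ROIs inside the brain mask."""
        brain = self.brain_mask()
        shape = self.grid_shape
        masks: dict[str, np.ndarray] = {}
        union = np.zeros(shape, dtype=bool)
        for name, center_frac, radius in self.roi_specs:
            center = np.asarray(center_frac, dtype=float) * (np.asarray(shape) - 1)
            if np.any(center - radius < 0) or np.any(center + radius > np.asarray(shape) - 1):
                raise ValueError(f"ROI {name!r} does not fit inside the grid {shape}")
            mask = _sphere(shape, center, float(radius))
            if not mask.any():
                raise ValueError(f"ROI {name!r} is empty")
            if not np.all(brain[mask]):
                raise ValueError(f"ROI {name!r} leaves the brain mask")
            if np.any(union & mask):
                raise ValueError(f"ROI {name!r} overlaps another ROI")
            union |= mask
            masks[name] = mask
        return masks

    def roi_union(self) -> np.ndarray:
        union = np.zeros(self.grid_shape, dtype=bool)
        for mask in self.roi_masks().values():
            union |= mask
        return union

    def template(self) -> np.ndarray:
        """Smooth baseline GM pattern: a quadratic dome over the brain mask."""
        shape = self.grid_shape
        grids = np.indices(shape, dtype=float)
        center = [(s - 1) / 2.0 for s in shape]
        semi = [0.42 * s for s in shape]
        dist2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
        tpl = np.where(dist2 <= 1.0, 0.45 + 0.25 * (1.0 - dist2), 0.0)
        return tpl

    def template_roi_mean(self) -> float:
        union = self.roi_union()
        return float(self.template()[union].mean())

    # ------------------------------------------------------------------ truth

    def true_indirect(self, outcome: str) -> float:
        """Recorded true indirect effect ``beta_vrf_gmv * beta_gmv_cog``."""
        return self.beta_vrf_gmv * self.beta_gmv_cog[outcome]

    def to_dict(self) -> dict:
        return {
            "group_names": list(self.group_names),
            "group_sizes": [int(n) for n in self.group_sizes],
            "vrf_prevalence": [list(map(float, row)) for row in self.vrf_prevalence],
            "beta_vrf_gmv": self.beta_vrf_gmv,
            "beta_gmv_cog": dict(self.beta_gmv_cog),
            "beta_direct": dict(self.beta_direct),
            "true_indirect": {k: self.true_indirect(k) for k in self.beta_gmv_cog},
            "noise_sd_image": self.noise_sd_image,
            "noise_sd_mediator": self.noise_sd_mediator,
            "noise_sd_cog": dict(self.noise_sd_cog),
            "smoothing_fwhm_mm": self.smoothing_fwhm_mm,
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": list(self.voxel_size_mm),
            "roi_specs": [
                [name, list(map(float, c)), float(r)] for name, c, r in self.roi_specs
            ],
            "group_atrophy": list(map(float, self.group_atrophy)),
            "mmse_baseline": self.mmse_baseline,
            "adascog_baseline": self.adascog_baseline,
            "seed": self.seed,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path


def generate_cohort(truth: GroundTruth) -> pd.DataFrame:
    """One row per subject: demographics, binary VRFs, mediator, cognition.

    Deterministic given ``truth.seed``; draws are ordered group-by-group so
    that changing one group's size does not perturb another group's rows.
    """
    ref = truth.template_roi_mean()
    prev = np.asarray(truth.vrf_prevalence, dtype=float)
    frames = []
    offset = 0
    for g, (gname, n) in enumerate(zip(truth.group_names, truth.group_sizes)):
        n = int(n)
        if n <= 0:
            raise ValueError(f"group {gname!r} has non-positive size {n}")
        rng = rng_for(truth.seed, "cohort", gname)
        age = rng.normal(_AGE_MEAN[g % 4], _AGE_SD[g % 4], n).round(1)
        gender = rng.binomial(1, _FEMALE_P[g % 4], n)
        apoe = rng.binomial(1, _APOE_P[g % 4], n)
        education = np.clip(rng.normal(16.0, 2.7, n), 6.0, 20.0).round(0)
        vrfs = rng.binomial(1, prev[g], size=(n, len(FACTORS)))
        score = vrfs.sum(axis=1).astype(float)
        eps_med = rng.normal(0.0, truth.noise_sd_mediator, n)
        mediator = ref + truth.beta_vrf_gmv * score + eps_med
        dev = mediator - ref
        cog: dict[str, np.ndarray] = {}
        for outcome in ("mmse", "adascog"):
            eps = rng.normal(0.0, truth.noise_sd_cog[outcome], n)
            base = truth.mmse_baseline if outcome == "mmse" else truth.adascog_baseline
            y = (
                base
                + truth.beta_gmv_cog[outcome] * dev
                + truth.beta_direct[outcome] * score
                + eps
            )
            cog[outcome] = y
        frame = pd.DataFrame(
            {
                "subject_id": [f"S{offset + i + 1:04d}" for i in range(n)],
                "group": gname,
                "group_index": g,
                "age": age,
                "gender": gender,
                "apoe": apoe,
                "education_years": education,
            }
        )
        for j, factor in enumerate(FACTORS):
            frame[f"vrf_{factor}"] = vrfs[:, j]
        frame["vrf_score"] = score
        frame["mediator_true"] = mediator
        frame["mmse"] = np.clip(cog["mmse"], 0.0, 30.0).round(2)
        frame["adascog"] = np.clip(cog["adascog"], 0.0, None).round(2)
        frames.append(frame)
        offset += n
    return pd.concat(frames, ignore_index=True)


@dataclass
class SyntheticImages:
    """Bundle returned by :func:`generate_gmv_images`."""

    images: list[VolumeImage]
    brain_mask: VolumeImage
    roi_masks: dict[str, np.ndarray]
    cohort: pd.DataFrame
    truth: GroundTruth


def generate_gmv_images(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    grid_shape: tuple[int, int, int] | None = None,
    voxel_size_mm: tuple[float, float, float] | None = None,
) -> SyntheticImages:
    """Per-subject GMV-like volumes plus the brain mask.

    The realized mediator (mean image value over each ROI and over their
    union) is computed from the generated images and stored back into the
    returned cohort copy as ``roi_mean_<name>`` / ``mediator_realized``.
    """
    if grid_shape is not None or voxel_size_mm is not None:
        truth = replace(
            truth,
            grid_shape=tuple(grid_shape) if grid_shape is not None else truth.grid_shape,
            voxel_size_mm=(
                tuple(voxel_size_mm) if voxel_size_mm is not None else truth.voxel_size_mm
            ),
        )
    template = truth.template()
    brain = truth.brain_mask()
    rois = truth.roi_masks()
    union = np.zeros(truth.grid_shape, dtype=bool)
    for m in rois.values():
        union |= m
    ref = truth.template_roi_mean()
    outside_roi = brain & ~union

    rng = rng_for(truth.seed, "images")
    images: list[VolumeImage] = []
    roi_means = {name: np.empty(len(cohort)) for name in rois}
    union_means = np.empty(len(cohort))
    dev = cohort["mediator_true"].to_numpy(dtype=float) - ref
    group_idx = cohort["group_index"].to_numpy(dtype=int)

    for i in range(len(cohort)):
        data = template.copy()
        data[outside_roi] += truth.group_atrophy[group_idx[i]]
        data[union] += dev[i]
        if truth.noise_sd_image > 0:
            noise = rng.standard_normal(truth.grid_shape)
            if truth.smoothing_fwhm_mm > 0:
                noise = smooth_gaussian(noise, truth.smoothing_fwhm_mm, truth.voxel_size_mm)
            noise *= truth.noise_sd_image / noise.std()
            data = data + noise
        img = VolumeImage(
            data,
            truth.voxel_size_mm,
            subject_id=str(cohort["subject_id"].iloc[i]),
        )
        images.append(img)
        for name, m in rois.items():
            roi_means[name][i] = data[m].mean()
        union_means[i] = data[union].mean()

    cohort_out = cohort.copy()
    for name in rois:
        cohort_out[f"roi_mean_{name}"] = roi_means[name]
    cohort_out["mediator_realized"] = union_means
    mask_img = VolumeImage(brain.astype(np.float32), truth.voxel_size_mm)
    return SyntheticImages(images, mask_img, rois, cohort_out, truth)


def make_mediation_dataset(
    n: int,
    a: float,
    b: float,
    c_prime: float = 0.0,
    seed: int = 0,
    sd_m: float = 1.0,
    sd_y: float = 1.0,
    x_levels: int = 6,
    x_p: float = 0.25,
) -> pd.DataFrame:
    """Small (X, M, Y) dataset with a known indirect effect ``a*b``.

    X mimics a composite risk count (binomial); used by calibration and
    type-I-error simulations that do not need images.
    """
    rng = rng_for(seed, "mediation-dataset")
    x = rng.binomial(x_levels, x_p, n).astype(float)
    m = a * x + rng.normal(0.0, sd_m, n)
    y = c_prime * x + b * m + rng.normal(0.0, sd_y, n)
    return pd.DataFrame({"x": x, "m": m, "y": y})
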