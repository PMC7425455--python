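"""3D scalar volumes: the common currency of the imaging stages.

A :class:`VolumeImage` is a plain 3D array plus voxel geometry.  NIfTI-1
round-tripping is delegated to nibabel; volumes are written RAS-oriented
with a diagonal affine built from the voxel size and origin offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeImage",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "smooth_gaussian",
    "stack_images",
]

# FWHM = sigma * 2*sqrt(2*ln 2)
_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian kernel standard deviation for a given full width at half maximum."""
    return float(fwhm) / _FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    return float(sigma) * _FWHM_PER_SIGMA


@dataclass
class VolumeImage:
    """A 3D scalar grid with voxel dimensions and an origin offset (mm)."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def like(self, data: np.ndarray, subject_id: str | None = None) -> "VolumeImage":
        """A new volume on this grid holding ``data``."""
        if data.shape != self.shape:
            raise ValueError(f"shape mismatch: {data.shape} vs {self.shape}")
        return VolumeImage(data, self.voxel_size_mm, self.origin_mm, subject_id)

    def same_grid(self, other: "VolumeImage") -> bool:
        return (
            self.shape == other.shape
            and self.voxel_size_mm == other.voxel_size_mm
            and self.origin_mm == other.origin_mm
        )

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms(self.voxel_size_mm)
        return img

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(self.to_nifti(), str(path))
        return path

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, subject_id: str | None = None) -> "VolumeImage":
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return cls(data, tuple(float(z) for z in zooms), origin, subject_id)

    @classmethod
    def load(cls, path: str | Path, subject_id: str | None = None) -> "VolumeImage":
        return cls.from_nifti(nib.load(str(path)), subject_id=subject_id)


def smooth_gaussian(
    data: np.ndarray,
    fwhm_mm: float | Sequence[float],
    voxel_size_mm: Sequence[float],
    mode: str = "wrap",
) -> np.ndarray:
    """Gaussian-smooth a 3D array to the requested FWHM (mm) per axis.

    ``mode='wrap'`` keeps the smoothed field stationary on the torus, which
    makes noise simulations and smoothness estimates edge-effect free.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ValueError("FWHM must be >= 0")
    sigma_vox = [fwhm_to_sigma(f) / v for f, v in zip(fwhm, voxel_size_mm)]
    if all(s == 0 for s in sigma_vox):
        return np.asarray(data, dtype=float).copy()
    return ndimage.gaussian_filter(np.asarray(data, dtype=float), sigma_vox, mode=mode)


def stack_images(images: Sequence[VolumeImage]) -> np.ndarray:
    """Stack a cohort of volumes into an (n, x, y, z) array, checking grids."""
    if len(images) == 0:
        raise ValueError("empty image list")
    ref = images[0]
    for im in images[1:]:
        if not ref.same_grid(im):
            raise ValueError("images are not on a common grid")
    return np.stack([im.data for im in images], axis=0)
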