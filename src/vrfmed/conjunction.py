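"""Conjunction of corrected binary maps and ROI mediator extraction."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cluster import connectivity_structure
from .images import VolumeImage, stack_images

__all__ = ["RoiSet", "conjunction", "split_rois", "extract_roi_means"]


@dataclass
class RoiSet:
    """Named, disjoint binary masks on a common grid."""

    masks: dict[str, np.ndarray]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("ROI masks are on different grids")
        for name, m in self.masks.items():
            if not m.any():
                raise ValueError(f"ROI {name!r} is empty")

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def label_volume(self) -> VolumeImage:
        """Integer-labeled volume (1..n in name order) for NIfTI export."""
        shape = next(iter(self.masks.values())).shape
        out = np.zeros(shape, dtype=np.int16)
        for i, mask in enumerate(self.masks.values(), start=1):
            out[mask] = i
        return VolumeImage(out.astype(np.float32), self.voxel_size_mm)

    def save(self, label_path: str | Path, names_path: str | Path) -> None:
        self.label_volume().save(label_path)
        Path(names_path).write_text(
            json.dumps({i + 1: name for i, name in enumerate(self.masks)}, indent=2)
        )


def conjunction(map_a: np.ndarray, map_b: np.ndarray) -> np.ndarray:
    """Voxel-wise logical AND of two binary maps on identical grids."""
    a = np.asarray(map_a, dtype=bool)
    b = np.asarray(map_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    return a & b


def split_rois(
    conj_map: np.ndarray,
    connectivity: int = 6,
    min_size: int = 1,
    voxel_size_mm: Sequence[float] = (2.0, 2.0, 2.0),
    names: Sequence[str] | None = None,
) -> RoiSet:
    """Connected components of a binary map become named ROIs.

    Components smaller than ``min_size`` voxels are dropped; default names
    are ROI_001, ROI_002, ... in decreasing component size.
    """
    conj_map = np.asarray(conj_map, dtype=bool)
    labels, n_lab = ndimage.label(conj_map, structure=connectivity_structure(connectivity))
    comps = []
    for lab in range(1, n_lab + 1):
        mask = labels == lab
        if mask.sum() >= min_size:
            comps.append(mask)
    comps.sort(key=lambda m: int(m.sum()), reverse=True)
    if names is not None:
        if len(names) < len(comps):
            raise ValueError("fewer names than components")
        keys = list(names[: len(comps)])
    else:
        keys = [f"ROI_{i + 1:03d}" for i in range(len(comps))]
    return RoiSet(dict(zip(keys, comps)), tuple(float(v) for v in voxel_size_mm))


def extract_roi_means(
    images: Sequence[VolumeImage] | np.ndarray,
    roiset: RoiSet,
    subject_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Subjects x ROIs table of mean image value over each ROI mask.

    This table is the mediator fed to the mediation stage.
    """
    if isinstance(images, np.ndarray):
        data4d = images
    else:
        data4d = stack_images(images)
        if subject_ids is None:
            subject_ids = [im.subject_id or f"subj_{i}" for i, im in enumerate(images)]
    if len(roiset) == 0:
        raise ValueError("empty RoiSet")
    shape = next(iter(roiset.masks.values())).shape
    if data4d.shape[1:] != shape:
        raise ValueError("images and ROI masks are on different grids")
    if subject_ids is None:
        subject_ids = [f"subj_{i}" for i in range(data4d.shape[0])]
    out = {"subject_id": list(subject_ids)}
    for name, mask in roiset.masks.items():
        out[name] = data4d[:, mask].mean(axis=1)
    return pd.DataFrame(out)
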