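"""Monte-Carlo cluster-extent thresholding.

Smoothness of the residual field is estimated from normalized first
differences; null smooth Gaussian fields are then simulated on the analysis
mask, and the (1 - alpha) quantile of the max-cluster-size distribution
gives the minimum extent a supra-threshold cluster must reach to be kept.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from ._rng import rng_for
from .glm import StatMap
from .images import VolumeImage, smooth_gaussian

__all__ = [
    "SmoothnessEstimate",
    "ClusterThresholdTable",
    "Cluster",
    "ClusterSet",
    "connectivity_structure",
    "estimate_smoothness",
    "simulate_cluster_null",
    "extract_clusters",
    "apply_cluster_correction",
]

_LN2_4 = 4.0 * math.log(2.0)


@dataclass
class SmoothnessEstimate:
    fwhm_mm: tuple[float, float, float]
    method: str = "gradient"

    @property
    def mean_fwhm_mm(self) -> float:
        return float(np.mean(self.fwhm_mm))


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D neighborhood structure for 6 / 18 / 26 connectivity."""
    try:
        order = {6: 1, 18: 2, 26: 3}[int(connectivity)]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, order)


def estimate_smoothness(
    residuals: np.ndarray | Sequence[np.ndarray],
    mask: VolumeImage | np.ndarray,
    voxel_size_mm: Sequence[float] = (2.0, 2.0, 2.0),
) -> SmoothnessEstimate:
    """Per-axis FWHM from the variance of first differences of residuals.

    Each residual image is standardized within the mask; along each axis the
    variance ``v`` of differences between in-mask neighbors satisfies, for a
    Gaussian autocorrelation, ``FWHM ~= voxel * sqrt(4 ln 2 / v)``.  Averaged
    over images.  Unsmoothed white noise yields ``v ~= 2`` and an apparent
    FWHM of ``1.18 x`` voxel size, the resolution floor of the estimator.
    """
    if isinstance(mask, VolumeImage):
        voxel_size_mm = mask.voxel_size_mm
        mask = mask.data.astype(bool)
    mask = np.asarray(mask, dtype=bool)
    resid = np.asarray(residuals, dtype=float)
    if resid.ndim == 3:
        resid = resid[None]
    if resid.shape[0] < 2:
        raise ValueError("need at least 2 residual images")
    if resid.shape[1:] != mask.shape:
        raise ValueError("residuals and mask are on different grids")

    var_diff = np.zeros(3)
    counts = np.zeros(3)
    for img in resid:
        vals = img[mask]
        sd = vals.std()
        if sd == 0:
            raise ValueError("constant residual image; smoothness undefined")
        std_img = (img - vals.mean()) / sd
        for ax in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[ax] = slice(1, None)
            sl_b[ax] = slice(None, -1)
            pair_mask = mask[tuple(sl_a)] & mask[tuple(sl_b)]
            diffs = (std_img[tuple(sl_a)] - std_img[tuple(sl_b)])[pair_mask]
            var_diff[ax] += (diffs**2).sum()
            counts[ax] += diffs.size
    if np.any(counts == 0):
        raise ValueError("mask too thin along some axis for difference-based estimation")
    v = var_diff / counts
    fwhm = tuple(float(d * math.sqrt(_LN2_4 / vi)) for d, vi in zip(voxel_size_mm, v))
    return SmoothnessEstimate(fwhm)


@dataclass
class ClusterThresholdTable:
    """Minimum cluster extents per (voxel-wise p, alpha) from a null simulation."""

    voxel_p: list[float]
    alpha: list[float]
    extents_voxels: dict[tuple[float, float], int]
    n_iterations: int
    seed: int
    connectivity: int
    voxel_volume_mm3: float
    fwhm_mm: float
    two_sided: bool = True
    max_sizes: dict[float, list[int]] = field(default_factory=dict, repr=False)

    def threshold_voxels(self, voxel_p: float, alpha: float) -> int:
        key = (float(voxel_p), float(alpha))
        if key not in self.extents_voxels:
            raise KeyError(f"(voxel_p={voxel_p}, alpha={alpha}) not in table")
        return self.extents_voxels[key]

    def threshold_mm3(self, voxel_p: float, alpha: float) -> float:
        return self.threshold_voxels(voxel_p, alpha) * self.voxel_volume_mm3

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "voxel_p": self.voxel_p,
            "alpha": self.alpha,
            "extents_voxels": [
                {"voxel_p": p, "alpha": a, "voxels": v, "mm3": v * self.voxel_volume_mm3}
                for (p, a), v in sorted(self.extents_voxels.items())
            ],
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "connectivity": self.connectivity,
            "voxel_volume_mm3": self.voxel_volume_mm3,
            "fwhm_mm": self.fwhm_mm,
            "two_sided": self.two_sided,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterThresholdTable":
        payload = json.loads(Path(path).read_text())
        extents = {
            (float(e["voxel_p"]), float(e["alpha"])): int(e["voxels"])
            for e in payload["extents_voxels"]
        }
        return cls(
            voxel_p=[float(p) for p in payload["voxel_p"]],
            alpha=[float(a) for a in payload["alpha"]],
            extents_voxels=extents,
            n_iterations=int(payload["n_iterations"]),
            seed=int(payload["seed"]),
            connectivity=int(payload["connectivity"]),
            voxel_volume_mm3=float(payload["voxel_volume_mm3"]),
            fwhm_mm=float(payload["fwhm_mm"]),
            two_sided=bool(payload["two_sided"]),
        )


def _extent_from_max_sizes(max_sizes: np.ndarray, alpha: float) -> int:
    """Smallest extent s (>= 1) with empirical P(max cluster >= s) <= alpha."""
    n = max_sizes.size
    for s in range(1, int(max_sizes.max()) + 2):
        if (max_sizes >= s).sum() / n <= alpha:
            return s
    return int(max_sizes.max()) + 1


def simulate_cluster_null(
    mask: VolumeImage | np.ndarray,
    fwhm_mm: float,
    voxel_p: float | Sequence[float],
    n_iter: int = 2000,
    seed: int = 0,
    connectivity: int = 6,
    alpha: float | Sequence[float] = 0.05,
    voxel_size_mm: Sequence[float] = (2.0, 2.0, 2.0),
    two_sided: bool = True,
) -> ClusterThresholdTable:
    """Tabulate null max-cluster-size quantiles for smooth Gaussian fields.

    Per iteration: white noise on the grid, smoothed to ``fwhm_mm``,
    standardized within the mask (so the voxel-wise threshold is exact under
    the null), thresholded at each voxel p, and the largest connected
    cluster recorded.  Deterministic given ``seed``.
    """
    if isinstance(mask, VolumeImage):
        voxel_size_mm = mask.voxel_size_mm
        mask = mask.data.astype(bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    voxel_ps = [float(p) for p in np.atleast_1d(voxel_p)]
    alphas = [float(a) for a in np.atleast_1d(alpha)]
    for p in voxel_ps:
        if not 0 < p < 1:
            raise ValueError("voxel_p must lie in (0, 1)")
    for a in alphas:
        if not 0 < a <= 1:
            raise ValueError("alpha must lie in (0, 1]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    structure = connectivity_structure(connectivity)
    thresholds = {
        p: (stats.norm.isf(p / 2.0) if two_sided else stats.norm.isf(p)) for p in voxel_ps
    }
    rng = rng_for(seed, "cluster-null")
    max_sizes = {p: np.zeros(n_iter, dtype=int) for p in voxel_ps}
    for it in range(n_iter):
        noise = rng.standard_normal(mask.shape)
        if fwhm_mm > 0:
            noise = smooth_gaussian(noise, fwhm_mm, voxel_size_mm)
        vals = noise[mask]
        field3d = np.zeros(mask.shape)
        field3d[mask] = (vals - vals.mean()) / vals.std()
        for p, thr in thresholds.items():
            supra = (np.abs(field3d) >= thr) if two_sided else (field3d >= thr)
            supra &= mask
            if not supra.any():
                continue
            labels, n_lab = ndimage.label(supra, structure=structure)
            if n_lab:
                sizes = np.bincount(labels.ravel())[1:]
                max_sizes[p][it] = int(sizes.max())

    extents = {}
    for p in voxel_ps:
        for a in alphas:
            extents[(p, a)] = _extent_from_max_sizes(max_sizes[p], a)
    return ClusterThresholdTable(
        voxel_p=voxel_ps,
        alpha=alphas,
        extents_voxels=extents,
        n_iterations=n_iter,
        seed=seed,
        connectivity=connectivity,
        voxel_volume_mm3=float(np.prod(voxel_size_mm)),
        fwhm_mm=float(fwhm_mm),
        two_sided=two_sided,
        max_sizes={p: max_sizes[p].tolist() for p in voxel_ps},
    )


@dataclass
class Cluster:
    label: int
    n_voxels: int
    volume_mm3: float
    peak_value: float
    peak_voxel: tuple[int, int, int]
    center_of_mass_voxel: tuple[float, float, float]
    voxels: np.ndarray  # (n_voxels, 3) integer indices


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float
    connectivity: int

    def __len__(self) -> int:
        return len(self.clusters)

    def label_map(self, shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=int)
        for c in self.clusters:
            out[tuple(c.voxels.T)] = c.label
        return out


def extract_clusters(
    stat_map: StatMap | np.ndarray,
    threshold: float,
    mask: np.ndarray | None = None,
    connectivity: int = 6,
    voxel_size_mm: Sequence[float] | None = None,
    two_sided: bool = False,
) -> ClusterSet:
    """Connected supra-threshold components, sizes in voxels and mm^3.

    With ``two_sided`` the threshold applies to ``|value|``; peak value is
    the in-cluster value of largest magnitude.
    """
    if isinstance(stat_map, StatMap):
        data = stat_map.data
        if mask is None:
            mask = stat_map.mask
        if voxel_size_mm is None:
            voxel_size_mm = stat_map.voxel_size_mm
    else:
        data = np.asarray(stat_map, dtype=float)
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    if voxel_size_mm is None:
        voxel_size_mm = (2.0, 2.0, 2.0)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    voxel_vol = float(np.prod(voxel_size_mm))
    supra = (np.abs(data) >= threshold) if two_sided else (data >= threshold)
    supra &= np.asarray(mask, dtype=bool)
    structure = connectivity_structure(connectivity)
    labels, n_lab = ndimage.label(supra, structure=structure)
    clusters = []
    for lab in range(1, n_lab + 1):
        idx = np.argwhere(labels == lab)
        vals = data[tuple(idx.T)]
        peak_i = int(np.argmax(np.abs(vals)) if two_sided else np.argmax(vals))
        clusters.append(
            Cluster(
                label=lab,
                n_voxels=idx.shape[0],
                volume_mm3=idx.shape[0] * voxel_vol,
                peak_value=float(vals[peak_i]),
                peak_voxel=tuple(int(v) for v in idx[peak_i]),
                center_of_mass_voxel=tuple(float(v) for v in idx.mean(axis=0)),
                voxels=idx,
            )
        )
    clusters.sort(key=lambda c: c.n_voxels, reverse=True)
    for new_lab, c in enumerate(clusters, start=1):
        c.label = new_lab
    return ClusterSet(clusters, float(threshold), connectivity)


def apply_cluster_correction(
    stat_map: StatMap,
    table: ClusterThresholdTable,
    voxel_p: float,
    alpha: float,
) -> tuple[np.ndarray, ClusterSet]:
    """Keep clusters at least as large as the tabulated extent (>= semantics).

    The map must be a z map (or any map on the standard-normal scale); the
    voxel threshold is derived from ``voxel_p`` with the table's sidedness.
    """
    if stat_map.kind not in ("z", "t"):
        raise ValueError(f"cluster correction expects a z (or t) map, got {stat_map.kind!r}")
    min_extent = table.threshold_voxels(voxel_p, alpha)
    thr = stats.norm.isf(voxel_p / 2.0) if table.two_sided else stats.norm.isf(voxel_p)
    clusters = extract_clusters(
        stat_map,
        thr,
        mask=stat_map.mask,
        connectivity=table.connectivity,
        voxel_size_mm=stat_map.voxel_size_mm,
        two_sided=table.two_sided,
    )
    surviving = [c for c in clusters.clusters if c.n_voxels >= min_extent]
    binary = np.zeros(stat_map.data.shape, dtype=bool)
    for c in surviving:
        binary[tuple(c.voxels.T)] = True
    kept = ClusterSet(surviving, clusters.threshold, clusters.connectivity)
    for new_lab, c in enumerate(kept.clusters, start=1):
        c.label = new_lab
    return binary, kept
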