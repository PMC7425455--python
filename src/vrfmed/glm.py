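"""Mass-univariate linear models on masked 3D volumes.

``fit_glm`` runs ordinary least squares at every in-mask voxel in one
matrix solve (contract: identical to a per-voxel OLS loop) and returns
slope / t / z maps for the predictor of interest.  ``fit_ancova`` computes
the partial F map comparing the group-dummy full model against the
covariate-only reduced model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .images import VolumeImage, stack_images

__all__ = [
    "DesignMatrix",
    "StatMap",
    "GlmResult",
    "build_design",
    "fit_glm",
    "fit_ancova",
    "t_to_z",
]


@dataclass
class DesignMatrix:
    """n x p predictor matrix; intercept first, predictor of interest second."""

    X: np.ndarray
    names: list[str]
    has_intercept: bool = True

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("design must be 2D")
        if self.X.shape[1] != len(self.names):
            raise ValueError("column names do not match design width")
        if self.X.shape[0] <= self.X.shape[1]:
            raise ValueError("need more observations than predictors")
        _check_rank(self.X, self.names)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.X, columns=self.names).to_csv(path, sep="\t", index=False)


@dataclass
class StatMap:
    """Per-voxel statistic image defined only inside its mask."""

    data: np.ndarray
    kind: str  # "beta" | "t" | "z" | "F" | "p"
    df: tuple[float, ...]
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("stat map and mask shapes differ")

    def to_volume(self) -> VolumeImage:
        return VolumeImage(self.data, self.voxel_size_mm)


@dataclass
class GlmResult:
    beta: StatMap
    t: StatMap
    z: StatMap
    residuals: np.ndarray  # (n, x, y, z), zero outside mask
    df_resid: int
    flagged_voxels: np.ndarray  # boolean 3D: zero residual variance


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via QR pivoting on the correlation scale
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        scale = diag.max() if diag.max() > 0 else 1.0
        bad = [names[j] for j in range(X.shape[1]) if diag[j] / scale < 1e-10]
        raise ValueError(f"design matrix is rank deficient (collinear columns: {bad or names})")


def build_design(
    cohort: pd.DataFrame,
    predictor: str,
    covariates: Sequence[str] = (),
    add_intercept: bool = True,
) -> DesignMatrix:
    """Design with intercept first, predictor of interest second, covariates after.

    The covariate name ``"group"`` expands to k-1 dummy columns (first group
    label, in order of appearance, is the reference level).  All other
    columns must already be numeric (gender and APOE carrier coded 0/1).
    """
    for col in [predictor, *[c for c in covariates if c != "group"]]:
        if col not in cohort.columns:
            raise ValueError(f"column {col!r} not in cohort")
    cols: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        cols.append(np.ones(len(cohort)))
        names.append("intercept")
    cols.append(cohort[predictor].to_numpy(dtype=float))
    names.append(predictor)
    for cov in covariates:
        if cov == "group":
            if "group" not in cohort.columns:
                raise ValueError("column 'group' not in cohort")
            labels = pd.unique(cohort["group"])
            for lab in labels[1:]:
                cols.append((cohort["group"] == lab).to_numpy(dtype=float))
                names.append(f"group_{lab}")
        else:
            cols.append(cohort[cov].to_numpy(dtype=float))
            names.append(cov)
    return DesignMatrix(np.column_stack(cols), names, has_intercept=add_intercept)


def t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Two-sided probability-preserving map from t(df) to a standard normal.

    The z value satisfies P(|Z| >= |z|) = P(|T| >= |t|); the sign of t is
    retained.  Infinite t maps to infinite z.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        p_half = stats.t.sf(np.abs(t), df)  # one-tail prob, preserved exactly
        z = stats.norm.isf(p_half)
    z = np.where(np.isinf(t), t, np.sign(t) * z)
    return z


def _prep(images, mask) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    if isinstance(images, np.ndarray):
        data4d = images
        voxel_size = (2.0, 2.0, 2.0)
    else:
        data4d = stack_images(images)
        voxel_size = images[0].voxel_size_mm
    if isinstance(mask, VolumeImage):
        mask_arr = mask.data.astype(bool)
        voxel_size = mask.voxel_size_mm
    else:
        mask_arr = np.asarray(mask, dtype=bool)
    if data4d.shape[1:] != mask_arr.shape:
        raise ValueError("images and mask are on different grids")
    return data4d, mask_arr, voxel_size


def fit_glm(
    images: Sequence[VolumeImage] | np.ndarray,
    mask: VolumeImage | np.ndarray,
    design: DesignMatrix,
    interest: int | str = 1,
) -> GlmResult:
    """OLS at every in-mask voxel; slope / t / z maps for one predictor.

    Voxels with exactly zero residual variance get ``t = +/-inf`` (sign of
    the slope, 0 if the slope is 0 too) and are flagged rather than dropped.
    """
    data4d, mask_arr, voxel_size = _prep(images, mask)
    X = design.X
    n, p = X.shape
    if data4d.shape[0] != n:
        raise ValueError(f"{data4d.shape[0]} images but {n} design rows")
    j = design.names.index(interest) if isinstance(interest, str) else int(interest)

    Y = data4d[:, mask_arr]  # n x V
    pinv = np.linalg.pinv(X)
    betas = pinv @ Y  # p x V
    resid = Y - X @ betas
    df = n - p
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    var_bj = sigma2 * xtx_inv[j, j]
    zero_var = rss <= np.finfo(float).eps * np.maximum((Y**2).sum(axis=0), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = betas[j] / np.sqrt(var_bj)
    t_vals = np.where(zero_var, np.sign(betas[j]) * np.inf, t_vals)
    t_vals = np.where(zero_var & (betas[j] == 0), 0.0, t_vals)
    z_vals = t_to_z(t_vals, df)

    def to_map(vals: np.ndarray, kind: str, dof: tuple[float, ...]) -> StatMap:
        full = np.zeros(mask_arr.shape)
        full[mask_arr] = vals
        return StatMap(full, kind, dof, mask_arr, voxel_size)

    resid4d = np.zeros_like(data4d, dtype=float)
    resid4d[:, mask_arr] = resid
    flagged = np.zeros(mask_arr.shape, dtype=bool)
    flagged[mask_arr] = zero_var
    return GlmResult(
        beta=to_map(betas[j], "beta", (float(df),)),
        t=to_map(t_vals, "t", (float(df),)),
        z=to_map(z_vals, "z", (float(df),)),
        residuals=resid4d,
        df_resid=df,
        flagged_voxels=flagged,
    )


def fit_ancova(
    images: Sequence[VolumeImage] | np.ndarray,
    mask: VolumeImage | np.ndarray,
    group_labels: Sequence,
    covariates: np.ndarray | None = None,
) -> StatMap:
    """Voxel-wise partial F: group dummies + covariates vs covariates only."""
    data4d, mask_arr, voxel_size = _prep(images, mask)
    labels = pd.Series(list(group_labels))
    n = len(labels)
    if data4d.shape[0] != n:
        raise ValueError("image count does not match group labels")
    uniq = list(pd.unique(labels))
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError("every group needs n >= 2")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    dummies = np.column_stack([(labels == lab).to_numpy(float) for lab in uniq[1:]])
    X_red = np.column_stack([np.ones(n), C])
    X_full = np.column_stack([X_red, dummies])
    p_full = X_full.shape[1]
    if n <= p_full:
        raise ValueError("need more subjects than full-model parameters")

    Y = data4d[:, mask_arr]
    rss_full = ((Y - X_full @ (np.linalg.pinv(X_full) @ Y)) ** 2).sum(axis=0)
    rss_red = ((Y - X_red @ (np.linalg.pinv(X_red) @ Y)) ** 2).sum(axis=0)
    df1 = k - 1
    df2 = n - p_full
    with np.errstate(divide="ignore", invalid="ignore"):
        f_vals = ((rss_red - rss_full) / df1) / (rss_full / df2)
    f_vals = np.where(rss_full == 0, np.inf, f_vals)
    f_vals = np.clip(f_vals, 0.0, None)  # guard tiny negative from roundoff
    full = np.zeros(mask_arr.shape)
    full[mask_arr] = f_vals
    return StatMap(full, "F", (float(df1), float(df2)), mask_arr, voxel_size)
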