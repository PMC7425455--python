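"""Three-regression mediation with Sobel test and case-resampling bootstrap.

The decomposition fits, by ordinary least squares with intercepts (and an
optional shared covariate set):

* total:    Y ~ X           -> c
* action:   M ~ X           -> a
* outcome:  Y ~ X + M       -> c', b

so that the indirect effect is ``a * b`` and, with identical covariates in
all three models, ``c = c' + a * b`` holds as an algebraic identity.
Significance of the indirect effect is assessed two ways: the delta-method
Sobel z and a percentile bootstrap CI from case resampling of subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream

logger = logging.getLogger(__name__)

__all__ = [
    "MediationPaths",
    "BootstrapResult",
    "MediationResult",
    "fit_mediation",
    "sobel_test",
    "bootstrap_indirect",
    "mediate",
    "run_mediation_panel",
]


@dataclass
class MediationPaths:
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    c_prime: float
    se_c_prime: float
    n: int

    @property
    def indirect(self) -> float:
        return self.a * self.b


@dataclass
class BootstrapResult:
    indirect: float
    ci_low: float
    ci_high: float
    boot_se: float
    n_boot: int
    seed: int
    ci_level: float
    significant: bool
    n_redrawn: int = 0


@dataclass
class MediationResult:
    paths: MediationPaths
    sobel_z: float
    sobel_p: float
    bootstrap: BootstrapResult | None = None
    roi: str = ""
    outcome: str = ""

    @property
    def indirect(self) -> float:
        return self.paths.indirect

    @property
    def significant(self) -> bool:
        return bool(self.bootstrap is not None and self.bootstrap.significant)


def _ols_slope(y: np.ndarray, predictors: np.ndarray, j: int) -> tuple[float, float]:
    """Slope j and its classical SE from OLS with the given predictor matrix."""
    n, p = predictors.shape
    coef, _, rank, _ = np.linalg.lstsq(predictors, y, rcond=None)
    if rank < p:
        raise ValueError("collinear predictors in mediation regression")
    resid = y - predictors @ coef
    df = n - p
    if df <= 0:
        raise ValueError("not enough observations for the regression")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(predictors.T @ predictors)
    return float(coef[j]), float(np.sqrt(sigma2 * xtx_inv[j, j]))


def _prep_xyz(x, m, y, covariates) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if m.size != n or y.size != n:
        raise ValueError("X, M, Y must have equal length")
    if np.ptp(x) == 0:
        raise ValueError("X is constant")
    if np.ptp(m) == 0:
        raise ValueError("M is constant")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariates must have one row per subject")
    return x, m, y, C


def fit_mediation(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> MediationPaths:
    """Fit the three regressions and return a, b, c, c' with SEs."""
    x, m, y, C = _prep_xyz(x, m, y, covariates)
    n = x.size
    ones = np.ones(n)
    X1 = np.column_stack([ones, x, C])
    c, se_c = _ols_slope(y, X1, 1)
    a, se_a = _ols_slope(m, X1, 1)
    X2 = np.column_stack([ones, x, m, C])
    c_prime, se_c_prime = _ols_slope(y, X2, 1)
    b, se_b = _ols_slope(y, X2, 2)
    return MediationPaths(a, se_a, b, se_b, c, se_c, c_prime, se_c_prime, n)


def sobel_test(
    a: float, se_a: float, b: float, se_b: float, second_order: bool = False
) -> tuple[float, float]:
    """Delta-method z test of the indirect effect a*b.

    First-order SE ``sqrt(b^2 se_a^2 + a^2 se_b^2)`` by default; the
    second-order variant adds ``se_a^2 se_b^2``.
    """
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be >= 0")
    var = b**2 * se_a**2 + a**2 * se_b**2
    if second_order:
        var += se_a**2 * se_b**2
    if a * b == 0:
        return 0.0, 1.0
    if var == 0:
        raise ValueError("Sobel denominator is zero with a*b != 0")
    z = (a * b) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def _boot_indirect_fast(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form a*b per replicate (no covariates). Returns (values, degenerate)."""
    xb = x[idx]
    mb = m[idx]
    yb = y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    mc = mb - mb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    sxx = (xc * xc).sum(axis=1)
    smm = (mc * mc).sum(axis=1)
    sxm = (xc * mc).sum(axis=1)
    sxy = (xc * yc).sum(axis=1)
    smy = (mc * yc).sum(axis=1)
    det = sxx * smm - sxm**2
    scale = np.maximum(sxx * smm, 1e-300)
    degenerate = (sxx <= 0) | (smm <= 0) | (det / scale < 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sxm / sxx
        b = (sxx * smy - sxm * sxy) / det
    return a * b, degenerate


def bootstrap_indirect(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Percentile bootstrap CI for a*b via case resampling of subjects.

    Degenerate replicates (constant X or M after resampling) are redrawn and
    counted; more than 10% redraws aborts.  Deterministic given ``seed``.
    """
    x, m, y, C = _prep_xyz(x, m, y, covariates)
    n = x.size
    if n < 10:
        raise ValueError("need n >= 10 subjects to bootstrap")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    rng = np.random.default_rng(substream(seed, "bootstrap"))
    point = fit_mediation(x, m, y, covariates if C.shape[1] else None).indirect

    estimates = np.empty(n_boot)
    n_redrawn = 0
    if C.shape[1] == 0:
        pending = np.arange(n_boot)
        while pending.size:
            idx = rng.integers(0, n, size=(pending.size, n))
            vals, bad = _boot_indirect_fast(x, m, y, idx)
            good = ~bad
            estimates[pending[good]] = vals[good]
            n_redrawn += int(bad.sum())
            if n_redrawn > 0.1 * n_boot:
                raise ValueError("more than 10% of bootstrap replicates were degenerate")
            pending = pending[bad]
    else:
        ones = np.ones(n)
        filled = 0
        while filled < n_boot:
            idx = rng.integers(0, n, size=n)
            xb, mb, yb, Cb = x[idx], m[idx], y[idx], C[idx]
            try:
                if np.ptp(xb) == 0 or np.ptp(mb) == 0:
                    raise ValueError("degenerate replicate")
                a_b, _ = _ols_slope(mb, np.column_stack([ones, xb, Cb]), 1)
                b_b, _ = _ols_slope(yb, np.column_stack([ones, xb, mb, Cb]), 2)
            except (ValueError, np.linalg.LinAlgError):
                n_redrawn += 1
                if n_redrawn > 0.1 * n_boot:
                    raise ValueError(
                        "more than 10% of bootstrap replicates were degenerate"
                    ) from None
                continue
            estimates[filled] = a_b * b_b
            filled += 1
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap replicates", n_redrawn)

    lo_q = (1.0 - ci_level) / 2.0
    ci_low = float(np.quantile(estimates, lo_q))
    ci_high = float(np.quantile(estimates, 1.0 - lo_q))
    significant = bool(ci_low > 0.0 or ci_high < 0.0)
    return BootstrapResult(
        indirect=point,
        ci_low=ci_low,
        ci_high=ci_high,
        boot_se=float(estimates.std(ddof=1)) if n_boot > 1 else 0.0,
        n_boot=n_boot,
        seed=seed,
        ci_level=ci_level,
        significant=significant,
        n_redrawn=n_redrawn,
    )


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
    roi: str = "",
    outcome: str = "",
) -> MediationResult:
    """Full single-mediator analysis: paths, Sobel test, bootstrap CI."""
    paths = fit_mediation(x, m, y, covariates)
    z, p = sobel_test(paths.a, paths.se_a, paths.b, paths.se_b)
    boot = bootstrap_indirect(x, m, y, covariates, n_boot=n_boot, seed=seed, ci_level=ci_level)
    return MediationResult(paths, z, p, boot, roi=roi, outcome=outcome)


def run_mediation_panel(
    cohort: pd.DataFrame,
    roi_means: pd.DataFrame,
    outcomes: Sequence[str] = ("mmse", "adascog"),
    x_col: str = "vrf_score",
    covariate_cols: Sequence[str] = (),
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> list[MediationResult]:
    """One MediationResult per (ROI x outcome), sorted by ROI label.

    Inputs are aligned on ``subject_id``; rows with missing values are
    dropped listwise with a logged count.  Each (ROI, outcome) cell draws
    its bootstrap from its own seed substream, so panel results do not
    depend on evaluation order.  No cross-ROI multiplicity correction is
    applied.
    """
    if "subject_id" not in cohort.columns or "subject_id" not in roi_means.columns:
        raise ValueError("both tables need a subject_id column")
    roi_cols = [c for c in roi_means.columns if c != "subject_id"]
    if not roi_cols:
        raise ValueError("roi_means has no ROI columns")
    merged = cohort.merge(roi_means, on="subject_id", how="inner", validate="1:1")
    needed = [x_col, *outcomes, *covariate_cols, *roi_cols]
    before = len(merged)
    merged = merged.dropna(subset=needed)
    if len(merged) < before:
        logger.info("dropped %d subjects with missing values", before - len(merged))
    x = merged[x_col].to_numpy(dtype=float)
    C = merged[list(covariate_cols)].to_numpy(dtype=float) if covariate_cols else None
    results = []
    for roi in sorted(roi_cols):
        m = merged[roi].to_numpy(dtype=float)
        for outcome in outcomes:
            y = merged[outcome].to_numpy(dtype=float)
            cell_seed = int(substream(seed, "panel", roi, outcome).generate_state(1)[0])
            results.append(
                mediate(
                    x,
                    m,
                    y,
                    covariates=C,
                    n_boot=n_boot,
                    seed=cell_seed,
                    ci_level=ci_level,
                    roi=roi,
                    outcome=outcome,
                )
            )
    return results


def panel_to_frame(results: Sequence[MediationResult]) -> pd.DataFrame:
    """Flatten panel results into a tidy table (one row per ROI x outcome)."""
    rows = []
    for r in results:
        rows.append(
            {
                "roi": r.roi,
                "outcome": r.outcome,
                "n": r.paths.n,
                "a": r.paths.a,
                "se_a": r.paths.se_a,
                "b": r.paths.b,
                "se_b": r.paths.se_b,
                "c": r.paths.c,
                "c_prime": r.paths.c_prime,
                "indirect": r.indirect,
                "sobel_z": r.sobel_z,
                "sobel_p": r.sobel_p,
                "boot_se": r.bootstrap.boot_se if r.bootstrap else np.nan,
                "ci_low": r.bootstrap.ci_low if r.bootstrap else np.nan,
                "ci_high": r.bootstrap.ci_high if r.bootstrap else np.nan,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
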