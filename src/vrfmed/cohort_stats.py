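"""Group-comparison statistics for the cohort table.

One-way ANOVA (raw and from summary statistics), Pearson chi-square for
categorical frequencies, Bonferroni-corrected pairwise post-hoc tests, and
partial correlation via explicit residualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "PairwiseResult",
    "summarize_groups",
    "anova_oneway",
    "anova_from_summary",
    "chi_square_counts",
    "posthoc_pairwise",
    "bonferroni_threshold",
    "partial_correlation",
]


@dataclass
class TestResult:
    """A test statistic with its degrees of freedom and p-value."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass
class PairwiseResult:
    """One post-hoc pairwise comparison under a family-corrected threshold."""

    pair: tuple[str, str]
    statistic: float
    df: float
    p: float
    threshold: float
    significant: bool


def summarize_groups(values: Sequence[np.ndarray] | Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Per-group n, mean, SD (ddof=1)."""
    items = values.items() if isinstance(values, Mapping) else enumerate(values)
    rows = []
    for label, v in items:
        v = np.asarray(v, dtype=float)
        rows.append(
            {"group": label, "n": v.size, "mean": v.mean(), "sd": v.std(ddof=1) if v.size > 1 else np.nan}
        )
    return pd.DataFrame(rows)


def _as_groups(values) -> list[np.ndarray]:
    if isinstance(values, Mapping):
        values = list(values.values())
    groups = [np.asarray(v, dtype=float) for v in values]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    return groups


def anova_oneway(values: Sequence[np.ndarray] | Mapping[str, np.ndarray]) -> TestResult:
    """Classical one-way ANOVA: between/within sum-of-squares decomposition."""
    groups = _as_groups(values)
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n_total = int(ns.sum())
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        raise ValueError("zero within-group variance everywhere; F undefined")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return TestResult("one-way ANOVA", f, (float(df_b), float(df_w)), p)


def anova_from_summary(
    ns: Sequence[int], means: Sequence[float], sds: Sequence[float]
) -> TestResult:
    """One-way ANOVA reconstructed from per-group (n, mean, SD).

    Algebraically identical to :func:`anova_oneway` on any raw data with
    these summaries: SSb = sum n_g (mean_g - grand)^2, SSw = sum (n_g-1) SD_g^2.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (ns.size == means.size == sds.size) or ns.size < 2:
        raise ValueError("need matching n/mean/SD for at least 2 groups")
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    if np.any(sds < 0):
        raise ValueError("SDs must be >= 0")
    k = ns.size
    n_total = ns.sum()
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        raise ValueError("zero within-group variance everywhere; F undefined")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return TestResult("one-way ANOVA (summary)", f, (float(df_b), float(df_w)), p)


def chi_square_counts(table: np.ndarray) -> TestResult:
    """Pearson chi-square of independence on an r x c count table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2D")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult("Pearson chi-square", float(chi2), (float(dof),), float(p))


def bonferroni_threshold(alpha_family: float, n_comparisons: int) -> float:
    """Per-comparison threshold alpha / m."""
    if n_comparisons <= 0:
        raise ValueError("number of comparisons must be positive")
    if not 0 < alpha_family <= 1:
        raise ValueError("alpha_family must lie in (0, 1]")
    return alpha_family / n_comparisons


def posthoc_pairwise(
    groups: Mapping[str, np.ndarray],
    alpha_family: float = 0.05,
    reference: str | None = None,
    equal_var: bool = False,
) -> list[PairwiseResult]:
    """Pairwise Welch t-tests at a Bonferroni-corrected threshold.

    With ``reference`` set, only the comparisons against that group are made
    (e.g., each of three milder groups against the most affected one, m = 3);
    otherwise all pairs are tested.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if reference is not None:
        if reference not in groups:
            raise ValueError(f"reference group {reference!r} not found")
        pairs = [(lab, reference) for lab in labels if lab != reference]
    else:
        pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    threshold = bonferroni_threshold(alpha_family, len(pairs))
    results = []
    for a, b in pairs:
        res = stats.ttest_ind(
            np.asarray(groups[a], float), np.asarray(groups[b], float), equal_var=equal_var
        )
        results.append(
            PairwiseResult(
                pair=(a, b),
                statistic=float(res.statistic),
                df=float(res.df),
                p=float(res.pvalue),
                threshold=threshold,
                significant=bool(res.pvalue < threshold),
            )
        )
    return results


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> TestResult:
    """Correlation of x and y after removing linear covariate effects.

    Both variables are regressed (with intercept) on the covariates; the
    Pearson correlation of the two residual vectors is returned with
    df = n - n_covariates - 2 and a two-sided t-based p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    k = c.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, covariates={k})")
    design = np.column_stack([np.ones(n), c])
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("x or y is constant after residualization")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - k - 2
    r_clipped = min(max(r, -1.0), 1.0)
    if abs(r_clipped) == 1.0:
        p = 0.0
    else:
        t = r_clipped * np.sqrt(df / (1.0 - r_clipped**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult("partial correlation", r, (float(df),), p)
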