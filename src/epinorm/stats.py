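"""Generic statistical tests used by the cohort summary and prevalence tables.

All group-comparison p-values in the reporting layer flow through this
module: uncorrected Pearson chi-square for categorical variables, one-way
ANOVA for continuous variables (from raw data or from published
(n, mean, SD) summaries), a Cochran--Armitage linear trend test for ordered
factors, and Benjamini--Hochberg FDR adjustment.

The chi-square is deliberately computed *without* Yates continuity
correction: the uncorrected statistic is the one that matches the table
engine conventions of the surrounding clinical-epidemiology literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyResult",
    "AnovaResult",
    "AnovaSummaryInput",
    "TrendResult",
    "pearson_chi2",
    "anova_oneway",
    "anova_from_summary",
    "trend_test",
    "bh_fdr",
]


@dataclass(frozen=True)
class ContingencyResult:
    observed: np.ndarray
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class AnovaSummaryInput:
    """Per-group summary moments: sample size, mean, SD (ddof=1)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"SD must be non-negative, got {self.sd}")


@dataclass(frozen=True)
class TrendResult:
    statistic: float  # signed z statistic
    p: float


def pearson_chi2(table) -> ContingencyResult:
    """Uncorrected Pearson chi-square test of independence on an r x c table.

    No continuity correction is applied, matching standard summary-table
    engines. Raises ``ValueError`` if any row or column marginal is zero.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError(f"expected an r x c table with r, c >= 2, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return ContingencyResult(observed=obs, chi2=float(chi2), df=int(df), p=float(p))


def anova_oneway(*groups: Sequence[float]) -> AnovaResult:
    """Classical one-way ANOVA on raw per-group values."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    for g in arrs:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    if all(np.var(g) == 0 for g in arrs):
        raise ValueError("zero within-group variance in all groups")
    F, p = sps.f_oneway(*arrs)
    df1 = len(arrs) - 1
    df2 = sum(g.size for g in arrs) - len(arrs)
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=float(p))


def anova_from_summary(groups: Sequence[AnovaSummaryInput]) -> AnovaResult:
    """One-way ANOVA computed from per-group (n, mean, SD) summaries.

    Algebraically identical to :func:`anova_oneway` on any raw data with
    matching moments: the between-group sum of squares is taken about the
    size-weighted grand mean and the within-group sum of squares is
    ``sum((n_i - 1) * sd_i**2)``.
    """
    groups = [g if isinstance(g, AnovaSummaryInput) else AnovaSummaryInput(*g) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    N = ns.sum()
    grand = (ns * means).sum() / N
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df1 = len(groups) - 1
    df2 = int(N) - len(groups)
    if ss_within == 0:
        raise ValueError("zero within-group variance in all groups")
    F = (ss_between / df1) / (ss_within / df2)
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=float(sps.f.sf(F, df1, df2)))


def trend_test(table, scores: Sequence[float] | None = None) -> TrendResult:
    """Cochran--Armitage test for linear trend on a 2 x k table of counts.

    Rows are the two groups, columns are k ordered categories. ``scores``
    defaults to the unit spacing 1..k. The statistic is the signed normal
    deviate; the p-value is two-sided.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] < 2:
        raise ValueError(f"expected a 2 x k table with k >= 2, got shape {obs.shape}")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in trend table")
    k = obs.shape[1]
    s = np.arange(1, k + 1, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    if s.size != k:
        raise ValueError("scores length must match number of columns")
    n_j = obs.sum(axis=0)       # column totals
    r1 = obs[0].sum()           # row-1 total
    N = obs.sum()
    p1 = r1 / N
    # T = sum_j s_j * (x_1j - expected); Var under H0 with fixed margins
    T = float((s * (obs[0] - p1 * n_j)).sum())
    var = p1 * (1 - p1) * (N * (s**2 * n_j).sum() - ((s * n_j).sum()) ** 2) / N
    if var <= 0:
        return TrendResult(statistic=0.0, p=1.0)
    z = T / np.sqrt(var)
    return TrendResult(statistic=float(z), p=float(2 * sps.norm.sf(abs(z))))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return q.reshape(p.shape)
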