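"""Region-wise case-control morphometry statistics.

Three analyses on FreeSurfer-style regional measures (cortical thickness
per Desikan ROI, subcortical/cerebellar volumes, intracranial volume):

* per-ROI ordinary least squares ``measure ~ group + age + sex + ICV``
  with the diagnosis indicator (0 = control, 1 = patient) as the predictor
  of interest, covariate-adjusted Cohen's d derived from the group
  t-statistic as ``d = t * sqrt(1/n1 + 1/n2)``, and Benjamini--Hochberg
  FDR within each measure family;
* a whole-brain *negative-deviation burden*: the percentage of a
  participant's regions with normative z below zero, regressed on group
  with the same covariates;
* a morphology--cognition Pearson correlation matrix with BH-FDR across
  all (region, feature) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "BurdenResult",
    "region_group_stats",
    "negative_z_burden",
    "morph_neuro_correlations",
]

DEFAULT_COVARIATES = ("age", "sex", "icv")


def _design(cohort: pd.DataFrame, icv: pd.Series | None, covariates) -> pd.DataFrame:
    """Assemble the regression design: intercept, group, covariates."""
    X = pd.DataFrame(index=cohort.index)
    X["intercept"] = 1.0
    X["group"] = (cohort["group"] == "patient").astype(float)
    for cov in covariates:
        if cov == "age":
            X["age"] = pd.to_numeric(cohort["age"])
        elif cov == "sex":
            X["sex"] = (cohort["sex"] == "male").astype(float)
        elif cov == "icv":
            if icv is None:
                raise ValueError("ICV covariate requested but no ICV column given")
            X["icv"] = pd.to_numeric(icv.reindex(cohort.index))
        else:
            X[cov] = pd.to_numeric(cohort[cov])
    return X


def _measure_family(roi: str) -> str:
    return "thickness" if str(roi).endswith("_thickness") else "volume"


def region_group_stats(morph: pd.DataFrame, cohort: pd.DataFrame,
                       icv: pd.Series | None = None,
                       covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Per-ROI covariate-adjusted group comparison with FDR.

    Returns one row per ROI column of ``morph``: measure family, the group
    regression coefficient (measure units), its t and two-sided p, the
    adjusted Cohen's d, the BH q (within measure family), and n_used.
    """
    common = morph.index.intersection(cohort.index)
    morph = morph.loc[common]
    X_full = _design(cohort.loc[common], icv, covariates)
    cov_ok = X_full.notna().all(axis=1)
    n_drop = int((~cov_ok).sum())
    if n_drop:
        logger.info("region_group_stats: dropping %d participants with missing covariates", n_drop)
    X_full = X_full.loc[cov_ok]
    morph = morph.loc[cov_ok]

    rows = []
    for roi in morph.columns:
        y = pd.to_numeric(morph[roi])
        ok = y.notna()
        X = X_full.loc[ok].to_numpy(float)
        yv = y.loc[ok].to_numpy(float)
        n, p = X.shape
        if np.linalg.matrix_rank(X) < p:
            raise ValueError(f"singular design matrix for ROI {roi!r} (collinear covariates)")
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        df = n - p
        sigma2 = float(resid @ resid) / df
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        g = 1  # group column position in the design
        t = beta[g] / se[g]
        pval = 2 * sps.t.sf(abs(t), df)
        n1 = int(X[:, g].sum())
        n0 = n - n1
        d = t * np.sqrt(1.0 / n0 + 1.0 / n1)
        rows.append({
            "roi": roi, "measure": _measure_family(roi), "beta": float(beta[g]),
            "t": float(t), "p": float(pval), "d": float(d), "n_used": n,
        })
    out = pd.DataFrame(rows).set_index("roi")
    out["q"] = np.nan
    for fam in out["measure"].unique():
        mask = out["measure"] == fam
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out


@dataclass
class BurdenResult:
    """Negative-z burden per participant and its group regression."""

    burden: pd.Series            # percent of regions with z < 0, per participant
    beta: float                  # group coefficient, percentage points
    conf_int: tuple[float, float]
    t: float
    df: int
    p: float
    intercept: float             # control-group-referenced level
    intercept_ci: tuple[float, float]
    r_squared: float
    model: object = None         # fitted statsmodels results


def negative_z_burden(morph_z, cohort: pd.DataFrame,
                      icv: pd.Series | None = None,
                      covariates=DEFAULT_COVARIATES) -> BurdenResult:
    """Percent of regions with negative normative z, regressed on group.

    The burden only uses the *sign* of each regional z, so it is invariant
    to any strictly monotone sign-preserving per-region transform.
    Participants with no observed regions are excluded (logged).
    """
    z = morph_z.z if hasattr(morph_z, "z") else morph_z
    n_obs = z.notna().sum(axis=1)
    excluded = n_obs[n_obs == 0].index.tolist()
    if excluded:
        logger.info("negative_z_burden: excluding participants with no regions: %s", excluded)
    kept = n_obs[n_obs > 0].index
    burden = 100.0 * (z.loc[kept] < 0).sum(axis=1) / n_obs.loc[kept]
    burden.name = "burden_pct"

    common = burden.index.intersection(cohort.index)
    X = _design(cohort.loc[common], icv, covariates)
    ok = X.notna().all(axis=1)
    X = X.loc[ok].drop(columns="intercept")
    y = burden.loc[common].loc[ok]
    model = sm.OLS(y, sm.add_constant(X)).fit()
    ci = model.conf_int()
    return BurdenResult(
        burden=burden,
        beta=float(model.params["group"]),
        conf_int=(float(ci.loc["group", 0]), float(ci.loc["group", 1])),
        t=float(model.tvalues["group"]),
        df=int(model.df_resid),
        p=float(model.pvalues["group"]),
        intercept=float(model.params["const"]),
        intercept_ci=(float(ci.loc["const", 0]), float(ci.loc["const", 1])),
        r_squared=float(model.rsquared),
        model=model,
    )


def morph_neuro_correlations(morph: pd.DataFrame, neuro_z, patients,
                             min_n: int = 4) -> pd.DataFrame:
    """Pearson correlations between regional measures and cognitive z-scores.

    One row per (region, feature) pair over the given patients: r, the
    two-sided p, the BH q across all computed pairs, and the pair n.
    Pairs with fewer than ``min_n`` overlapping observations or a constant
    vector are skipped (logged).
    """
    z = neuro_z.z if hasattr(neuro_z, "z") else neuro_z
    patients = [p for p in patients if p in morph.index and p in z.index]
    morph = morph.loc[patients]
    z = z.loc[patients]
    rows = []
    for roi in morph.columns:
        for feat in z.columns:
            pair = pd.concat([morph[roi], z[feat]], axis=1).dropna()
            if len(pair) < min_n:
                logger.info("correlations: skipping (%s, %s): n=%d < %d",
                            roi, feat, len(pair), min_n)
                continue
            a = pair.iloc[:, 0].to_numpy(float)
            b = pair.iloc[:, 1].to_numpy(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                logger.info("correlations: skipping (%s, %s): constant vector", roi, feat)
                continue
            r, p = sps.pearsonr(a, b)
            rows.append({"roi": roi, "feature": feat, "r": float(r),
                         "p": float(p), "n": len(pair)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out
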