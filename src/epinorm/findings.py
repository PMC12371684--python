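"""Neuroradiological finding taxonomy and tabular reporting.

Coded radiological findings are organized in a three-category taxonomy:

* ``epilepsy_related`` — lesions with known epileptogenic potential
  (malformations of cortical development, heterotopia, cavernoma,
  neoplasm, supratentorial encephalomalacia or old stroke);
* ``unknown`` — abnormalities whose relationship to focal epilepsy is not
  established (white matter hyperintensities, asymmetric amygdala or
  hippocampus, supratentorial arachnoid cysts, cortical atrophy, ...);
* ``incidental`` — findings also reported in asymptomatic people with no
  link to seizures (developmental venous anomalies, infratentorial
  lesions, non-arachnoid cysts, enlarged ventricles, ...).

A participant's overall MRI conclusion is *abnormal* when they carry any
epilepsy-related or unknown-category finding; participants with only
incidental findings are concluded normal. Categories are non-exclusive at
the participant level, so category percentages need not sum to 100.

The module also provides the summary-table engine (Mean (SD) / n (%) rows
with ANOVA, chi-square, or trend tests per variable) and the per-epoch
seizure-outcome tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import anova_oneway, pearson_chi2, trend_test

__all__ = [
    "FindingCode", "VOCABULARY", "CATEGORIES",
    "conclusions", "category_prevalence", "cohort_summary", "outcome_tabulation",
    "OutcomeSummary",
]

CATEGORIES = ("epilepsy_related", "unknown", "incidental")


@dataclass(frozen=True)
class FindingCode:
    code: str
    label: str
    category: str
    notes: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for code {self.code!r}")


def _vocab(entries) -> dict[str, FindingCode]:
    out = {}
    for code, label, category, *notes in entries:
        out[code] = FindingCode(code, label, category, notes[0] if notes else "")
    return out


#: Shipped finding vocabulary. Supratentorial arachnoid cysts default to
#: the unknown category (possible causal links to epilepsy) unless
#: overridden per participant after EEG localizes seizures elsewhere.
VOCABULARY: dict[str, FindingCode] = _vocab([
    ("epilepsy_single_lesion", "Epilepsy-related single lesion", "epilepsy_related"),
    ("epilepsy_cavernoma", "Cavernoma", "epilepsy_related"),
    ("epilepsy_neoplasm", "Neoplasm", "epilepsy_related"),
    ("epilepsy_mcd", "Malformation of cortical development", "epilepsy_related"),
    ("epilepsy_heterotopia", "Heterotopia", "epilepsy_related"),
    ("epilepsy_supratentorial_old_stroke", "Supratentorial old stroke", "epilepsy_related"),
    ("epilepsy_supratentorial_encephalomalacia", "Supratentorial encephalomalacia",
     "epilepsy_related"),
    ("unknown_single_lesion", "Single lesion, unknown significance", "unknown"),
    ("unknown_multiple_lesions", "Multiple lesions, unknown significance", "unknown"),
    ("unknown_supratentorial_hyperintensity", "Supratentorial hyperintensity", "unknown"),
    ("unknown_arachnoid_cyst", "Supratentorial arachnoid cyst", "unknown",
     "unknown relationship unless ruled out by EEG"),
    ("unknown_supratentorial_neoplasm", "Other supratentorial neoplasm", "unknown"),
    ("unknown_asymmetric_amygdala", "Asymmetric amygdala", "unknown"),
    ("unknown_asymmetric_hippocampus", "Asymmetric hippocampus", "unknown"),
    ("unknown_amygdala_hippocampus_hyperintensity",
     "Amygdala/hippocampus hyperintensity", "unknown"),
    ("unknown_cortical_atrophy", "Cortical atrophy", "unknown"),
    ("unknown_white_matter_hyperintensities", "White matter hyperintensities", "unknown"),
    ("unknown_other", "Other, unknown significance", "unknown"),
    ("incidental_single_lesion", "Incidental single lesion", "incidental"),
    ("incidental_multiple_lesions", "Incidental multiple lesions", "incidental"),
    ("incidental_developmental_venous_anomaly",
     "Isolated developmental venous anomaly", "incidental"),
    ("incidental_infratentorial_old_stroke", "Infratentorial old stroke", "incidental"),
    ("incidental_infratentorial_encephalomalacia",
     "Infratentorial encephalomalacia", "incidental"),
    ("incidental_non_arachnoid_cyst", "Non-arachnoid cyst", "incidental"),
    ("incidental_enlarged_asymmetric_ventricles",
     "Enlarged or asymmetric ventricles", "incidental"),
    ("incidental_cavum_septum_vergae", "Cavum septum pellucidum/vergae", "incidental"),
    ("incidental_dilated_perivascular_spaces", "Dilated perivascular spaces", "incidental"),
    ("incidental_other", "Other incidental finding", "incidental"),
])


def _code_category(code: str, pid=None, overrides=None) -> str:
    if overrides and (pid, code) in overrides:
        return overrides[(pid, code)]
    if code not in VOCABULARY:
        raise KeyError(f"unknown finding code {code!r}")
    return VOCABULARY[code].category


def conclusions(findings: pd.DataFrame, overrides: dict | None = None) -> pd.Series:
    """Per-participant overall MRI conclusion (normal/abnormal).

    Abnormal iff the participant carries any finding whose category is
    epilepsy_related or unknown; incidental-only readings conclude normal.
    ``overrides`` maps (participant, code) to a category, supporting e.g.
    re-classification of an arachnoid cyst as incidental after EEG.
    """
    for code in findings.columns:
        if code not in VOCABULARY:
            raise KeyError(f"unknown finding code {code!r}")
    out = {}
    for pid, row in findings.iterrows():
        cats = {_code_category(c, pid, overrides) for c, v in row.items() if bool(v) is True}
        out[pid] = "abnormal" if cats & {"epilepsy_related", "unknown"} else "normal"
    return pd.Series(out, name="conclusion")


def category_prevalence(findings: pd.DataFrame, cohort: pd.DataFrame,
                        overrides: dict | None = None) -> dict[str, pd.DataFrame]:
    """Prevalence of each taxonomy category and each code, by group.

    A participant counts once per category no matter how many codes they
    carry within it; categories overlap so percentages need not sum to
    100. Returns ``{"categories": ..., "codes": ...}`` with per-group
    counts, percentages, and uncorrected chi-square p-values. The
    ``categories`` table also carries the overall conclusion row.
    """
    common = findings.index.intersection(cohort.index)
    findings = findings.loc[common].fillna(False).astype(bool)
    groups = cohort.loc[common, "group"]
    concl = conclusions(findings, overrides)

    member = pd.DataFrame(index=findings.index)
    for cat in CATEGORIES:
        # overrides are per-participant, so membership is computed row-wise
        member[cat] = [
            any(bool(findings.at[pid, c]) and _code_category(c, pid, overrides) == cat
                for c in findings.columns)
            for pid in findings.index
        ]
    member["normal_conclusion"] = concl == "normal"
    member["abnormal_conclusion"] = concl == "abnormal"

    def _group_rows(indicator: pd.Series) -> dict:
        row = {}
        tab = []
        for g in ("control", "patient"):
            sub = indicator[groups == g]
            n, tot = int(sub.sum()), int(sub.size)
            row[f"{g}_n"] = n
            row[f"{g}_total"] = tot
            row[f"{g}_pct"] = 100.0 * n / tot if tot else np.nan
            tab.append([n, tot - n])
        try:
            row["p"] = pearson_chi2(np.array(tab)).p
        except ValueError:
            row["p"] = np.nan
        return row

    cat_rows = {name: _group_rows(member[name]) for name in member.columns}
    code_rows = {code: _group_rows(findings[code]) for code in findings.columns}
    return {
        "categories": pd.DataFrame(cat_rows).T.rename_axis("category"),
        "codes": pd.DataFrame(code_rows).T.rename_axis("code"),
    }


def cohort_summary(cohort: pd.DataFrame, variables: dict[str, str],
                   group_col: str = "group") -> pd.DataFrame:
    """Summary-table engine: per-variable descriptives and group tests.

    ``variables`` maps column name to its declared type: ``continuous``
    (Mean (SD), range; ANOVA), ``categorical`` (n (%); chi-square), or
    ``ordered`` (n (%); trend test on the category order of the column,
    which should be an ordered categorical or sortable). Missing values
    are counted as N-Miss and excluded from tests.
    """
    group_levels = sorted(cohort[group_col].dropna().unique())
    rows = []
    for var, vtype in variables.items():
        if vtype not in ("continuous", "categorical", "ordered"):
            raise ValueError(f"variable {var!r} has undeclared/unknown type {vtype!r}")
        col = cohort[var]
        n_miss = int(col.isna().sum())
        base = {"variable": var, "type": vtype, "n_miss": n_miss}
        if vtype == "continuous":
            groups = [pd.to_numeric(col[cohort[group_col] == g]).dropna().to_numpy()
                      for g in group_levels]
            try:
                p = anova_oneway(*groups).p
            except ValueError:
                p = np.nan
            row = dict(base)
            for g, vals in zip(group_levels, groups):
                row[f"{g}_summary"] = (
                    f"{np.mean(vals):.3f} ({np.std(vals, ddof=1):.3f})" if vals.size >= 2 else "NA"
                )
            row["p"] = p
            rows.append(row)
        else:
            if isinstance(col.dtype, pd.CategoricalDtype) and col.cat.ordered:
                levels = list(col.cat.categories)
            else:
                levels = sorted(col.dropna().unique(), key=str)
            tab = np.array([[int(((col == lv) & (cohort[group_col] == g)).sum())
                             for lv in levels] for g in group_levels])
            try:
                if vtype == "ordered":
                    p = trend_test(tab).p
                else:
                    p = pearson_chi2(tab).p
            except ValueError:
                p = np.nan
            for j, lv in enumerate(levels):
                row = dict(base)
                row["level"] = lv
                for i, g in enumerate(group_levels):
                    tot = tab[i].sum()
                    row[f"{g}_summary"] = (
                        f"{tab[i, j]} ({100.0 * tab[i, j] / tot:.1f}%)" if tot else "0"
                    )
                row["p"] = p if j == 0 else np.nan  # report test once per variable
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class OutcomeSummary:
    """Per-epoch seizure-freedom proportions and outcome consistency."""

    per_epoch: pd.DataFrame          # epoch, n_sf, n_observed, sf_pct
    always_sf_pct: float
    always_ps_pct: float
    mixed_pct: float
    n_included: int                  # patients with >= 1 observed epoch
    counts: dict = field(default_factory=dict)


def outcome_tabulation(grid: pd.DataFrame) -> OutcomeSummary:
    """Tabulate SF/PS outcome sequences, ignoring missing epochs.

    ``grid`` is patients x epochs with entries 'SF', 'PS', or missing.
    Per-epoch proportions are over non-missing labels; consistency classes
    (always-SF / always-PS / mixed) partition the patients with at least
    one observed epoch, judged on observed epochs only.
    """
    if grid.shape[1] < 1:
        raise ValueError("need at least one epoch")
    valid = {"SF", "PS"}
    observed = grid.isin(valid)
    per_epoch = pd.DataFrame({
        "n_sf": (grid == "SF").sum(),
        "n_observed": observed.sum(),
    })
    per_epoch["sf_pct"] = 100.0 * per_epoch["n_sf"] / per_epoch["n_observed"].replace(0, np.nan)
    per_epoch.index.name = "epoch"

    any_obs = observed.any(axis=1)
    included = grid.loc[any_obs]
    n_inc = int(any_obs.sum())
    always_sf = int(((included == "SF") | ~included.isin(valid)).all(axis=1).sum())
    always_ps = int(((included == "PS") | ~included.isin(valid)).all(axis=1).sum())
    mixed = n_inc - always_sf - always_ps
    pct = lambda x: 100.0 * x / n_inc if n_inc else np.nan
    return OutcomeSummary(
        per_epoch=per_epoch,
        always_sf_pct=pct(always_sf), always_ps_pct=pct(always_ps), mixed_pct=pct(mixed),
        n_included=n_inc,
        counts={"always_sf": always_sf, "always_ps": always_ps, "mixed": mixed},
    )
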