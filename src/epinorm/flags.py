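"""Directional abnormality flags from normative z-scores.

Each feature carries a direction: ``higher_worse`` (e.g. depression and
anxiety questionnaires, reaction times) or ``lower_worse`` (cognitive and
motor performance). A participant is flagged abnormal on a feature when
their z-score deviates beyond T SD in the *worse* direction:

    higher_worse:  z > T        lower_worse:  z < -T

Inequalities are strict, and the threshold T is interpreted as a deviation
magnitude in both directions (so ``lower_worse`` at T = 2 means z < -2, a
score two SD below the normative centre). T = 2 is the primary clinical
threshold; T = 1 is the liberal ancillary one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .stats import pearson_chi2

__all__ = [
    "HIGHER_WORSE", "LOWER_WORSE", "NEUROPSYCH_DIRECTIONS",
    "FlagTable", "AbnormalityFlagger", "flag_abnormal", "prevalence_table",
]

HIGHER_WORSE = "higher_worse"
LOWER_WORSE = "lower_worse"

#: Directions of the 13 standard neuropsychological features: mood scores
#: and reaction times are worse when high, performance indices when low.
NEUROPSYCH_DIRECTIONS: dict[str, str] = {
    "Depression PHQ9": HIGHER_WORSE,
    "Anxiety GAD7": HIGHER_WORSE,
    "Visual RT M": HIGHER_WORSE,
    "Visual RT SD": HIGHER_WORSE,
    "Finger Tapping RH": LOWER_WORSE,
    "Finger Tapping LH": LOWER_WORSE,
    "Auditory Memory": LOWER_WORSE,
    "Delayed Memory": LOWER_WORSE,
    "Immediate Memory": LOWER_WORSE,
    "Visual Memory": LOWER_WORSE,
    "Working Memory": LOWER_WORSE,
    "Processing Speed": LOWER_WORSE,
    "Executive Function": LOWER_WORSE,
}


@dataclass
class FlagTable:
    """Boolean (nullable) participants x features flag matrix."""

    flags: pd.DataFrame  # dtype "boolean", <NA> where z missing
    threshold: float
    direction: dict[str, str]


class AbnormalityFlagger:
    """Thin transformer turning a z matrix into directional flags.

    Parameters
    ----------
    direction : feature name -> {"higher_worse", "lower_worse"}
    threshold : T > 0, SD units (2 primary, 1 ancillary)
    """

    def __init__(self, direction: Mapping[str, str] | None = None, threshold: float = 2.0):
        self.direction = direction
        self.threshold = threshold

    def fit(self, X=None, y=None):
        return self

    def transform(self, z: pd.DataFrame) -> pd.DataFrame:
        return self.transform_full(z).flags

    def transform_full(self, z: pd.DataFrame) -> FlagTable:
        direction = dict(self.direction if self.direction is not None else NEUROPSYCH_DIRECTIONS)
        return flag_abnormal(z, direction, self.threshold)

    def get_params(self, deep=True):
        return {"direction": self.direction, "threshold": self.threshold}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


def flag_abnormal(z: pd.DataFrame, direction: Mapping[str, str], threshold: float = 2.0) -> FlagTable:
    """Flag z-deviations beyond ``threshold`` SD in each feature's worse direction."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    z = z.z if hasattr(z, "z") else z
    missing_dir = [c for c in z.columns if c not in direction]
    if missing_dir:
        raise ValueError(f"no direction declared for features: {missing_dir}")
    bad_dir = {c: d for c, d in direction.items()
               if c in z.columns and d not in (HIGHER_WORSE, LOWER_WORSE)}
    if bad_dir:
        raise ValueError(f"unknown direction values: {bad_dir}")
    flags = pd.DataFrame(index=z.index, columns=z.columns, dtype="boolean")
    for col in z.columns:
        vals = z[col]
        if direction[col] == HIGHER_WORSE:
            raw = vals > threshold
        else:
            raw = vals < -threshold
        flags[col] = raw.astype("boolean").mask(vals.isna())
    return FlagTable(flags=flags, threshold=float(threshold),
                     direction={c: direction[c] for c in z.columns})


def prevalence_table(flag_table: FlagTable | pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-feature flag prevalence by group with a chi-square comparison.

    ``cohort`` must carry a ``group`` column indexed by participant id.
    Percentages are computed over non-missing flags; the group test is the
    uncorrected Pearson chi-square on the flagged/not-flagged x group
    table, reported as NaN when a group has no non-missing flags or the
    table is degenerate (e.g. nobody flagged anywhere).
    """
    flags = flag_table.flags if isinstance(flag_table, FlagTable) else flag_table
    common = flags.index.intersection(cohort.index)
    if len(common) == 0:
        raise ValueError("flag table and cohort share no participants")
    flags = flags.loc[common]
    groups = cohort.loc[common, "group"]
    rows = []
    for feat in flags.columns:
        row: dict = {"feature": feat}
        counts = {}
        for g in ("control", "patient"):
            sub = flags.loc[groups == g, feat]
            obs = sub.dropna()
            n_flagged = int(obs.sum())
            n_total = int(obs.size)
            pct = 100.0 * n_flagged / n_total if n_total else np.nan
            row[f"{g}_flagged"] = n_flagged
            row[f"{g}_n"] = n_total
            row[f"{g}_pct"] = pct
            counts[g] = (n_flagged, n_total - n_flagged)
        table = np.array([counts["control"], counts["patient"]])
        try:
            row["p"] = pearson_chi2(table).p
        except ValueError:
            row["p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
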