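"""Participant-specific normative z-scores by repeated control subsampling.

Rather than standardizing against the single control mean and SD, each
participant's score is referenced to an ensemble of small control
subsamples: draw B random subsamples of m healthy controls, record each
subsample's mean and SD, and form

    z = (score - mean of the B subsample means) / (mean of the B subsample SDs)

When the participant being scored is themselves a control, their own value
is excluded from every subsample, so a control's z never reflects their
own score. The averaged small-sample SD is slightly larger than the full
control SD (Jensen), which makes these z-scores mildly conservative
relative to naive standardization.

Randomness is keyed per (seed, participant, feature), so results do not
depend on the order in which participants or features are processed.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "ResamplingSpec",
    "ZMatrix",
    "NormativeZScorer",
    "normative_z",
    "enumerate_normative",
]

_ENUMERATION_CAP = 1_000_000


@dataclass(frozen=True)
class ResamplingSpec:
    """Parameters of the control-subsampling scheme.

    n_resamples : B, number of independent subsamples (default 100).
    subsample_size : m, controls per subsample, drawn without replacement
        (default 10).
    seed : base seed; per-(participant, feature) streams are derived from it.
    sd_ddof : 1 for the n-1 (sample) SD denominator, 0 for n.
    """

    n_resamples: int = 100
    subsample_size: int = 10
    seed: int = 0
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.subsample_size < 1:
            raise ValueError("subsample_size must be >= 1")
        if self.subsample_size == 1 and self.sd_ddof == 1:
            raise ValueError("subsample_size 1 is incompatible with the n-1 SD denominator")
        if self.sd_ddof not in (0, 1):
            raise ValueError("sd_ddof must be 0 or 1")


@dataclass
class ZMatrix:
    """Result container: z-scores plus the normative centre/scale used.

    ``centre`` and ``scale`` have the same shape as ``z`` because controls
    are scored leave-self-out, so their normative reference differs from
    the patients'.
    """

    z: pd.DataFrame
    centre: pd.DataFrame
    scale: pd.DataFrame
    spec: ResamplingSpec
    degenerate_features: list = field(default_factory=list)


def _stream(seed: int, participant, feature) -> np.random.Generator:
    """Deterministic, order-independent RNG per (participant, feature)."""
    key = [
        int(seed) & 0xFFFFFFFF,
        zlib.crc32(str(participant).encode()),
        zlib.crc32(str(feature).encode()),
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def _subsample_moments(values: np.ndarray, B: int, m: int, ddof: int,
                       rng: np.random.Generator) -> tuple[float, float]:
    """Mean of B subsample means and mean of B subsample SDs."""
    n = values.size
    # B independent m-subsets without replacement: rank B rows of uniforms
    idx = np.argsort(rng.random((B, n)), axis=1, kind="stable")[:, :m]
    sub = values[idx]
    return float(sub.mean(axis=1).mean()), float(sub.std(axis=1, ddof=ddof).mean())


class NormativeZScorer(BaseEstimator, TransformerMixin):
    """Transformer computing resampling-based normative z-scores.

    Fit on the control participants' feature table (rows indexed by
    participant id); transform any participant table sharing the feature
    columns. Rows of the transform input whose index matches a fitted
    control are scored leave-self-out.

    Parameters mirror :class:`ResamplingSpec`.
    """

    def __init__(self, n_resamples: int = 100, subsample_size: int = 10,
                 seed: int = 0, sd_ddof: int = 1):
        self.n_resamples = n_resamples
        self.subsample_size = subsample_size
        self.seed = seed
        self.sd_ddof = sd_ddof

    @property
    def _spec(self) -> ResamplingSpec:
        return ResamplingSpec(self.n_resamples, self.subsample_size, self.seed, self.sd_ddof)

    def fit(self, X: pd.DataFrame, y=None) -> "NormativeZScorer":
        X = _as_frame(X)
        self._spec  # validate parameters
        m = self.subsample_size
        for col in X.columns:
            n_ok = int(X[col].notna().sum())
            if n_ok < m + 1:
                raise ValueError(
                    f"feature {col!r}: {n_ok} non-missing controls, "
                    f"need >= {m + 1} for leave-self-out subsampling"
                )
        self.controls_ = X.copy()
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.transform_full(X).z

    def transform_full(self, X: pd.DataFrame) -> ZMatrix:
        """Like :meth:`transform` but returns the full :class:`ZMatrix`."""
        if not hasattr(self, "controls_"):
            raise ValueError("NormativeZScorer is not fitted")
        X = _as_frame(X)
        missing_cols = [c for c in X.columns if c not in self.controls_.columns]
        if missing_cols:
            raise ValueError(f"features not seen in fit: {missing_cols}")
        spec = self._spec
        B, m, ddof = spec.n_resamples, spec.subsample_size, spec.sd_ddof
        z = pd.DataFrame(np.nan, index=X.index, columns=X.columns, dtype=float)
        centre = z.copy()
        scale = z.copy()
        degenerate: set = set()

        control_ids = self.controls_.index
        for feat in X.columns:
            col = self.controls_[feat]
            avail = col[col.notna()]
            # sort by id so the draw does not depend on input row order
            avail = avail.loc[sorted(avail.index, key=str)]
            for pid in X.index:
                score = X.at[pid, feat]
                if pd.isna(score):
                    continue
                if pid in control_ids:
                    pool = avail.drop(index=pid, errors="ignore")
                else:
                    pool = avail
                if pool.size < m:
                    degenerate.add(feat)
                    continue
                rng = _stream(spec.seed, pid, feat)
                c, s = _subsample_moments(pool.to_numpy(float), B, m, ddof, rng)
                centre.at[pid, feat] = c
                scale.at[pid, feat] = s
                if s <= 0 or not math.isfinite(s):
                    degenerate.add(feat)
                    continue
                z.at[pid, feat] = (score - c) / s

        for feat in sorted(degenerate):
            msg = f"feature {feat!r}: degenerate normative scale; affected z set to missing"
            logger.warning(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
        return ZMatrix(z=z, centre=centre, scale=scale, spec=spec,
                       degenerate_features=sorted(degenerate))


def normative_z(scores: pd.DataFrame, controls, spec: ResamplingSpec | None = None) -> ZMatrix:
    """Score every participant in ``scores`` against the control subset.

    ``controls`` is an iterable of participant ids (a subset of the index
    of ``scores``). Controls are scored with their own row excluded from
    every subsample.
    """
    spec = spec or ResamplingSpec()
    scores = _as_frame(scores)
    controls = list(controls)
    unknown = [c for c in controls if c not in scores.index]
    if unknown:
        raise ValueError(f"control ids not in the score table: {unknown}")
    scorer = NormativeZScorer(spec.n_resamples, spec.subsample_size, spec.seed, spec.sd_ddof)
    scorer.fit(scores.loc[controls])
    return scorer.transform_full(scores)


def enumerate_normative(values, m: int, sd_ddof: int = 1,
                        cap: int = _ENUMERATION_CAP) -> tuple[float, float]:
    """Exact normative (centre, scale) by enumerating every m-subset.

    Brute-force oracle for the sampled estimator: returns the mean over all
    C(n, m) subsamples of the subsample mean, and of the subsample SD.
    Only feasible for small control pools; raises if the subset count
    exceeds ``cap``.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    n = vals.size
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")
    if m == 1 and sd_ddof == 1:
        raise ValueError("SD undefined for singleton subsamples with the n-1 denominator")
    n_subsets = math.comb(n, m)
    if n_subsets > cap:
        raise ValueError(
            f"C({n}, {m}) = {n_subsets} exceeds the enumeration cap {cap}; "
            "use the sampled estimator instead"
        )
    idx = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), m)),
        dtype=np.intp, count=n_subsets * m,
    ).reshape(n_subsets, m)
    sub = vals[idx]
    return float(sub.mean(axis=1).mean()), float(sub.std(axis=1, ddof=sd_ddof).mean())


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D participants x features table")
    return pd.DataFrame(arr)
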