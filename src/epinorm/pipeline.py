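"""End-to-end orchestration: configuration, file I/O, and the full run.

A run is described by a :class:`RunConfig` (YAML/JSON-loadable): either
paths to the four input tables (cohort, neuropsychology, morphometry,
findings) or a ``simulate`` block, plus the resampling parameters, flag
thresholds, clustering range, covariates, and FDR level. All tables are
UTF-8 TSV with ``NA`` as the missing-value token; every run writes a
manifest recording the configuration hash, seed, and package version so
identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .findings import VOCABULARY, category_prevalence, cohort_summary, outcome_tabulation
from .flags import NEUROPSYCH_DIRECTIONS, flag_abnormal, prevalence_table
from .morphometry import morph_neuro_correlations, negative_z_burden, region_group_stats
from .normative import ResamplingSpec, normative_z
from .profiles import CognitiveProfiler, pca_projection
from .simulate import SimConfig, THICKNESS_ROIS, VOLUME_STRUCTURES, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "read_morphometry_tables", "read_table", "load_inputs"]

MISSING_TOKEN = "NA"
_ICV_ALIASES = {"EstimatedTotalIntraCranialVol", "eTIV", "ICV"}
_SUMMARY_COLUMNS = {"BrainSegVolNotVent", "lh_MeanThickness_thickness",
                    "rh_MeanThickness_thickness"}


@dataclass
class RunConfig:
    """Pipeline configuration; either ``inputs`` paths or a simulate block."""

    inputs: dict | None = None            # cohort/neuropsych/morphometry/findings paths
    simulate: SimConfig | None = None
    resampling: ResamplingSpec = field(default_factory=ResamplingSpec)
    thresholds: tuple = (2.0, 1.0)
    k_range: tuple = (1, 2, 3, 4, 5, 6, 7, 8)
    k: int | None = None
    n_init: int = 25
    covariates: tuple = ("age", "sex", "icv")
    fdr_q: float = 0.05
    outdir: str | None = None
    seed: int = 0
    plots: bool = False

    def __post_init__(self):
        if self.inputs is None and self.simulate is None:
            self.simulate = SimConfig(seed=self.seed)
        if self.inputs is not None and self.simulate is not None:
            raise ValueError("give input paths or a simulate block, not both")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        for t in self.thresholds:
            if t <= 0:
                raise ValueError("flag thresholds must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            if "finding_prevalence" in sim:
                sim["finding_prevalence"] = {
                    tuple(k.split("|")): v for k, v in sim["finding_prevalence"].items()
                }
            raw["simulate"] = SimConfig(**sim)
        if "resampling" in raw:
            raw["resampling"] = ResamplingSpec(**raw["resampling"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim["finding_prevalence"] = {
                f"{c}|{g}": p for (c, g), p in self.simulate.finding_prevalence.items()
            }
            out["simulate"] = sim
        return out

    def digest(self) -> str:
        payload = self.to_jsonable()
        payload.pop("outdir", None)  # output location does not change the analysis
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def read_table(path, index_col: int = 0) -> pd.DataFrame:
    """Read a UTF-8 TSV with 'NA' missing tokens, indexed by participant."""
    df = pd.read_csv(path, sep="\t", index_col=index_col, na_values=[MISSING_TOKEN],
                     keep_default_na=False, encoding="utf-8")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated participant ids {dupes}")
    return df


def read_morphometry_tables(paths) -> tuple[pd.DataFrame, pd.Series | None]:
    """Read and merge FreeSurfer-style stats tables (thickness/volume TSVs).

    Each table has one participant column (first) and one column per ROI,
    as produced by the standard stats-table exporters. ROI names are
    normalized to hemisphere-prefixed Desikan labels with a ``_thickness``
    suffix for thickness tables; the intracranial volume column (eTIV /
    EstimatedTotalIntraCranialVol) is split out. Unknown ROI columns are
    passed through with a warning; duplicated participants are an error.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    icv = None
    for path in paths:
        df = read_table(path)
        is_thickness = "thickness" in str(df.index.name or "").lower() or any(
            str(c).endswith("_thickness") for c in df.columns
        )
        renames = {}
        for col in df.columns:
            name = str(col)
            if name in _ICV_ALIASES:
                continue
            if is_thickness and not name.endswith("_thickness") \
                    and f"{name}_thickness" in THICKNESS_ROIS:
                renames[col] = f"{name}_thickness"
        df = df.rename(columns=renames)
        for col in df.columns:
            name = str(col)
            if name in _ICV_ALIASES:
                series = pd.to_numeric(df[name])
                icv = series if icv is None else icv.combine_first(series)
                df = df.drop(columns=[col])
                continue
            if name not in THICKNESS_ROIS and name not in VOLUME_STRUCTURES \
                    and name not in _SUMMARY_COLUMNS:
                warnings.warn(f"{path}: unrecognized ROI column {name!r} passed through",
                              RuntimeWarning, stacklevel=2)
        frames.append(df)
    merged = pd.concat(frames, axis=1)
    if merged.columns.duplicated().any():
        raise ValueError("duplicate ROI columns across morphometry tables")
    merged.index.name = "participant_id"
    if icv is not None:
        icv = icv.rename("EstimatedTotalIntraCranialVol")
    return merged.apply(pd.to_numeric), icv


def load_inputs(config: RunConfig):
    """Materialize (cohort, neuropsych, morphometry, icv, findings, directions)."""
    if config.simulate is not None:
        sim = simulate_cohort(config.simulate)
        return sim.cohort, sim.neuropsych, sim.morphometry, sim.icv, \
            sim.findings, sim.directions
    paths = config.inputs
    required = {"cohort", "neuropsych", "morphometry", "findings"}
    missing = required - set(paths)
    if missing:
        raise ValueError(f"missing input paths: {sorted(missing)}")
    cohort = read_table(paths["cohort"])
    if "group" not in cohort.columns:
        raise ValueError(f"{paths['cohort']}: no 'group' column")
    bad = set(cohort["group"].dropna()) - {"control", "patient"}
    if bad:
        raise ValueError(f"{paths['cohort']}: unknown group labels {sorted(bad)}")
    neuropsych = read_table(paths["neuropsych"])
    morph_paths = paths["morphometry"]
    morphometry, icv = read_morphometry_tables(morph_paths)
    findings = read_table(paths["findings"]).astype(bool)
    unknown_codes = [c for c in findings.columns if c not in VOCABULARY]
    if unknown_codes:
        raise ValueError(f"{paths['findings']}: unknown finding codes {unknown_codes}")
    directions = {c: NEUROPSYCH_DIRECTIONS[c] for c in neuropsych.columns
                  if c in NEUROPSYCH_DIRECTIONS}
    undeclared = [c for c in neuropsych.columns if c not in NEUROPSYCH_DIRECTIONS]
    if undeclared:
        raise ValueError(f"features without a declared direction: {undeclared}")
    return cohort, neuropsych, morphometry, icv, findings, directions


@dataclass
class PipelineResult:
    """Everything one full run produces."""

    config: RunConfig
    cohort: pd.DataFrame
    neuro_z: object                      # ZMatrix
    flags: dict                          # threshold -> FlagTable
    flag_prevalence: dict                # threshold -> DataFrame
    profiler: CognitiveProfiler
    profile_means: pd.DataFrame
    profile_sizes: pd.Series
    pca_coords: pd.DataFrame
    pca_explained: np.ndarray
    region_stats: pd.DataFrame
    morph_z: object                      # ZMatrix
    burden: object                       # BurdenResult
    correlations: pd.DataFrame
    findings_report: dict
    summary_table: pd.DataFrame
    outcome_summary: object
    manifest: dict


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    """Run every analysis stage and (optionally) write all artifacts."""
    config = config or RunConfig()
    cohort, neuropsych, morphometry, icv, findings, directions = load_inputs(config)
    controls = cohort.index[cohort["group"] == "control"]
    patients = cohort.index[cohort["group"] == "patient"]

    spec = dataclasses.replace(config.resampling, seed=config.seed)
    neuro_z = normative_z(neuropsych, controls, spec)

    flags = {}
    flag_prev = {}
    for t in config.thresholds:
        ft = flag_abnormal(neuro_z.z, directions, t)
        flags[t] = ft
        flag_prev[t] = prevalence_table(ft, cohort)

    profiler = CognitiveProfiler(k=config.k, k_range=config.k_range,
                                 n_init=config.n_init, seed=config.seed)
    profiler.fit(neuro_z.z.loc[patients])
    profile_means, profile_sizes = profiler.profile_summary(neuro_z.z.loc[patients])
    coords, explained = pca_projection(profiler.scaled_)

    region_stats = region_group_stats(morphometry, cohort, icv, config.covariates)
    morph_z = normative_z(morphometry, controls, spec)
    burden = negative_z_burden(morph_z, cohort, icv, config.covariates)
    correlations = morph_neuro_correlations(morphometry, neuro_z, patients)

    findings_report = category_prevalence(findings, cohort)
    summary_vars = {"age": "continuous", "sex": "categorical", "education": "categorical"}
    summary_table = cohort_summary(cohort, summary_vars)
    outcome_cols = [c for c in cohort.columns if c.startswith("outcome_")]
    outcome_summary = outcome_tabulation(cohort.loc[patients, outcome_cols]) \
        if outcome_cols else None

    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "n_controls": int(len(controls)),
        "n_patients": int(len(patients)),
        "thresholds": list(config.thresholds),
        "chosen_k": int(profiler.k_),
        "elbow_suggestion": int(profiler.elbow_k_),
        "degenerate_features": list(neuro_z.degenerate_features),
    }

    result = PipelineResult(
        config=config, cohort=cohort, neuro_z=neuro_z, flags=flags,
        flag_prevalence=flag_prev, profiler=profiler, profile_means=profile_means,
        profile_sizes=profile_sizes, pca_coords=coords, pca_explained=explained,
        region_stats=region_stats, morph_z=morph_z, burden=burden,
        correlations=correlations, findings_report=findings_report,
        summary_table=summary_table, outcome_summary=outcome_summary,
        manifest=manifest,
    )
    if config.outdir is not None:
        write_results(result, config.outdir)
    return result


def write_results(result: PipelineResult, outdir) -> None:
    """Write all result tables as TSV plus the JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(outdir / f"{name}.tsv", sep="\t", na_rep=MISSING_TOKEN, encoding="utf-8")

    _tsv(result.neuro_z.z, "neuro_z")
    for t, ft in result.flags.items():
        tag = f"{t:g}sd"
        _tsv(ft.flags.astype("boolean").astype(object)
             .map(lambda v: int(v) if v is not pd.NA and v == v else pd.NA), f"flags_{tag}")
        _tsv(result.flag_prevalence[t], f"flag_prevalence_{tag}")
    _tsv(result.profile_means, "profile_means")
    _tsv(result.profile_sizes.to_frame("n"), "profile_sizes")
    _tsv(result.pca_coords.assign(profile=result.profiler.labels_), "pca_projection")
    _tsv(result.region_stats, "region_stats")
    _tsv(result.morph_z.z, "morph_z")
    _tsv(result.burden.burden.to_frame(), "burden")
    _tsv(result.correlations, "morph_neuro_correlations")
    _tsv(result.findings_report["categories"], "finding_categories")
    _tsv(result.findings_report["codes"], "finding_codes")
    _tsv(result.summary_table, "cohort_summary")
    if result.outcome_summary is not None:
        _tsv(result.outcome_summary.per_epoch, "outcome_per_epoch")
        consistency = pd.DataFrame([{
            "always_sf_pct": result.outcome_summary.always_sf_pct,
            "always_ps_pct": result.outcome_summary.always_ps_pct,
            "mixed_pct": result.outcome_summary.mixed_pct,
            "n_included": result.outcome_summary.n_included,
        }])
        consistency.to_csv(outdir / "outcome_consistency.tsv", sep="\t",
                           index=False, na_rep=MISSING_TOKEN)
    burden_model = {
        "beta": result.burden.beta, "ci": list(result.burden.conf_int),
        "t": result.burden.t, "df": result.burden.df, "p": result.burden.p,
        "intercept": result.burden.intercept,
        "intercept_ci": list(result.burden.intercept_ci),
        "r_squared": result.burden.r_squared,
    }
    (outdir / "burden_model.json").write_text(json.dumps(burden_model, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))

    if result.config.plots:
        from . import plotting

        primary_t = result.config.thresholds[0]
        plotting.radar_plot(result.flag_prevalence[primary_t], outdir / "flag_radar.svg")
        plotting.elbow_plot(result.profiler.wcss_curve_, outdir / "elbow.svg",
                            suggested_k=result.profiler.elbow_k_)
        plotting.pca_plot(result.pca_coords, result.profiler.labels_,
                          result.pca_explained, outdir / "pca_overlap.svg")
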