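"""Synthetic case-control cohort generator with planted ground truth.

Generates the four tables the analysis pipeline consumes — cohort
demographics and seizure outcomes, a neuropsychological feature matrix, a
regional morphometry matrix with intracranial volume, and a coded
radiological findings table — for a newly-diagnosed focal epilepsy style
study (default 104 patients vs 45 controls).

The statistical structure is deliberately simple and fully declared:

* neuropsychological features are multivariate Gaussian with a single
  common "deficit" factor (pairwise correlation ``feature_correlation``),
  shifted in patients by ``feature_effects`` in control-SD units; the
  default shifts are calibrated so that the expected >2 SD flag rates
  match those observed in newly-diagnosed focal epilepsy cohorts
  (e.g. about half of patients flagged on depression/anxiety);
* regional thickness/volume values are Gaussian with a mild age slope and
  an ICV association (ICV itself is sex-dependent), with patient shifts
  ``region_effects`` (default: -0.4 SD thinning in eight frontal ROIs);
* findings are independent Bernoulli draws per (code, group) prevalence,
  defaulting to prevalences typical of 3T research-protocol readings;
* seizure outcomes follow a first-order Markov chain over 6-month epochs
  with element-wise missingness.

All randomness flows from one integer seed through a single generator, so
identical configurations reproduce byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .findings import VOCABULARY
from .flags import NEUROPSYCH_DIRECTIONS

__all__ = ["SimConfig", "SimResult", "simulate_cohort", "plant_profiles", "write_tables"]

#: Desikan cortical parcellation labels (34 per hemisphere).
DESIKAN_LABELS = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
]

THICKNESS_ROIS = [f"{h}_{lab}_thickness" for h in ("lh", "rh") for lab in DESIKAN_LABELS]

#: Subcortical / cerebellar volume structures with typical (mean, SD) mm^3.
VOLUME_STRUCTURES = {
    "Left-Thalamus": (7500, 800), "Right-Thalamus": (7400, 800),
    "Left-Caudate": (3600, 450), "Right-Caudate": (3700, 450),
    "Left-Putamen": (5200, 600), "Right-Putamen": (5100, 600),
    "Left-Pallidum": (1900, 250), "Right-Pallidum": (1850, 250),
    "Left-Hippocampus": (4200, 450), "Right-Hippocampus": (4300, 450),
    "Left-Amygdala": (1700, 220), "Right-Amygdala": (1750, 220),
    "Left-Accumbens-area": (600, 110), "Right-Accumbens-area": (620, 110),
    "Left-Cerebellum-Cortex": (53000, 5500), "Right-Cerebellum-Cortex": (54000, 5500),
}

#: Frontal-lobe thickness ROIs carrying the default planted thinning.
FRONTAL_ROIS = [
    "lh_precentral_thickness", "lh_rostralmiddlefrontal_thickness",
    "lh_superiorfrontal_thickness", "rh_caudalmiddlefrontal_thickness",
    "rh_paracentral_thickness", "rh_parsopercularis_thickness",
    "rh_rostralmiddlefrontal_thickness", "rh_superiorfrontal_thickness",
]

#: Default patient-minus-control shifts (control-SD units), calibrated via
#: the Gaussian tail so expected >2 SD flag rates match typical observed
#: prevalences (depression ~49%, anxiety ~54%, executive ~18%, ...).
DEFAULT_FEATURE_EFFECTS = {
    "Depression PHQ9": 2.00, "Anxiety GAD7": 2.10,
    "Visual RT M": 1.05, "Visual RT SD": 0.80,
    "Finger Tapping RH": -0.10, "Finger Tapping LH": -0.33,
    "Auditory Memory": -0.33, "Delayed Memory": -0.92,
    "Immediate Memory": -0.66, "Visual Memory": -0.83,
    "Working Memory": -0.43, "Processing Speed": -0.85,
    "Executive Function": -1.09,
}

#: Raw-score location/scale used to de-standardize each feature.
FEATURE_SCALES = {
    "Depression PHQ9": (4.0, 3.5), "Anxiety GAD7": (3.5, 3.2),
    "Visual RT M": (420.0, 60.0), "Visual RT SD": (85.0, 25.0),
    "Finger Tapping RH": (58.0, 7.0), "Finger Tapping LH": (54.0, 7.0),
    "Auditory Memory": (100.0, 15.0), "Delayed Memory": (100.0, 15.0),
    "Immediate Memory": (100.0, 15.0), "Visual Memory": (100.0, 15.0),
    "Working Memory": (100.0, 15.0), "Processing Speed": (100.0, 15.0),
    "Executive Function": (100.0, 15.0),
}

DEFAULT_REGION_EFFECTS = {roi: -0.4 for roi in FRONTAL_ROIS}

#: Default per-(code, group) finding probabilities, typical of research
#: 3T readings of newly diagnosed focal epilepsy patients and controls.
DEFAULT_FINDING_PREVALENCE = {
    ("epilepsy_single_lesion", "control"): 0.067, ("epilepsy_single_lesion", "patient"): 0.106,
    ("epilepsy_cavernoma", "control"): 0.022, ("epilepsy_cavernoma", "patient"): 0.0,
    ("epilepsy_neoplasm", "control"): 0.0, ("epilepsy_neoplasm", "patient"): 0.038,
    ("epilepsy_mcd", "control"): 0.0, ("epilepsy_mcd", "patient"): 0.029,
    ("epilepsy_heterotopia", "control"): 0.0, ("epilepsy_heterotopia", "patient"): 0.019,
    ("epilepsy_supratentorial_old_stroke", "control"): 0.0,
    ("epilepsy_supratentorial_old_stroke", "patient"): 0.010,
    ("epilepsy_supratentorial_encephalomalacia", "control"): 0.044,
    ("epilepsy_supratentorial_encephalomalacia", "patient"): 0.029,
    ("unknown_single_lesion", "control"): 0.333, ("unknown_single_lesion", "patient"): 0.490,
    ("unknown_multiple_lesions", "control"): 0.022,
    ("unknown_multiple_lesions", "patient"): 0.144,
    ("unknown_supratentorial_hyperintensity", "control"): 0.022,
    ("unknown_supratentorial_hyperintensity", "patient"): 0.029,
    ("unknown_arachnoid_cyst", "control"): 0.044, ("unknown_arachnoid_cyst", "patient"): 0.038,
    ("unknown_supratentorial_neoplasm", "control"): 0.0,
    ("unknown_supratentorial_neoplasm", "patient"): 0.010,
    ("unknown_asymmetric_amygdala", "control"): 0.0,
    ("unknown_asymmetric_amygdala", "patient"): 0.048,
    ("unknown_asymmetric_hippocampus", "control"): 0.0,
    ("unknown_asymmetric_hippocampus", "patient"): 0.019,
    ("unknown_amygdala_hippocampus_hyperintensity", "control"): 0.0,
    ("unknown_amygdala_hippocampus_hyperintensity", "patient"): 0.038,
    ("unknown_cortical_atrophy", "control"): 0.044,
    ("unknown_cortical_atrophy", "patient"): 0.038,
    ("unknown_white_matter_hyperintensities", "control"): 0.244,
    ("unknown_white_matter_hyperintensities", "patient"): 0.394,
    ("unknown_other", "control"): 0.0, ("unknown_other", "patient"): 0.019,
    ("incidental_single_lesion", "control"): 0.156, ("incidental_single_lesion", "patient"): 0.231,
    ("incidental_multiple_lesions", "control"): 0.0,
    ("incidental_multiple_lesions", "patient"): 0.048,
    ("incidental_developmental_venous_anomaly", "control"): 0.044,
    ("incidental_developmental_venous_anomaly", "patient"): 0.019,
    ("incidental_infratentorial_old_stroke", "control"): 0.0,
    ("incidental_infratentorial_old_stroke", "patient"): 0.058,
    ("incidental_infratentorial_encephalomalacia", "control"): 0.0,
    ("incidental_infratentorial_encephalomalacia", "patient"): 0.010,
    ("incidental_non_arachnoid_cyst", "control"): 0.022,
    ("incidental_non_arachnoid_cyst", "patient"): 0.058,
    ("incidental_enlarged_asymmetric_ventricles", "control"): 0.0,
    ("incidental_enlarged_asymmetric_ventricles", "patient"): 0.038,
    ("incidental_cavum_septum_vergae", "control"): 0.0,
    ("incidental_cavum_septum_vergae", "patient"): 0.019,
    ("incidental_dilated_perivascular_spaces", "control"): 0.0,
    ("incidental_dilated_perivascular_spaces", "patient"): 0.029,
    ("incidental_other", "control"): 0.089, ("incidental_other", "patient"): 0.038,
}


def _default_transition():
    # rows: previous state (SF, PS); columns: next state (SF, PS)
    return ((0.85, 0.15), (0.25, 0.75))


@dataclass
class SimConfig:
    """Generator configuration; defaults are the study conditions emulated."""

    n_patients: int = 104
    n_controls: int = 45
    seed: int = 0
    feature_effects: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_EFFECTS))
    feature_correlation: float = 0.3
    region_effects: dict = field(default_factory=lambda: dict(DEFAULT_REGION_EFFECTS))
    missing_rate: float = 0.10
    finding_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_FINDING_PREVALENCE))
    outcome_transition: tuple = field(default_factory=_default_transition)
    outcome_initial_sf: float = 0.567
    n_epochs: int = 4
    age_range: tuple = (16.0, 70.0)
    control_age: tuple = (40.75, 15.7)
    patient_age: tuple = (35.78, 13.5)
    male_prob: float = 0.545
    highschool_prob: float = 0.60

    def __post_init__(self):
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("n_patients and n_controls must both be >= 2")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError(f"missing_rate must be in [0, 1], got {self.missing_rate}")
        if not -1 < self.feature_correlation < 1:
            raise ValueError("feature_correlation must lie in (-1, 1)")
        if not 0 <= self.outcome_initial_sf <= 1:
            raise ValueError("outcome_initial_sf must be a probability")
        tm = np.asarray(self.outcome_transition, dtype=float)
        if tm.shape != (2, 2) or (tm < 0).any() or (tm > 1).any() \
                or not np.allclose(tm.sum(axis=1), 1.0):
            raise ValueError("outcome_transition must be a 2x2 row-stochastic matrix")
        for (code, group), prob in self.finding_prevalence.items():
            if code not in VOCABULARY:
                raise ValueError(f"unknown finding code {code!r} in finding_prevalence")
            if not 0 <= prob <= 1:
                raise ValueError(f"invalid probability {prob} for {(code, group)}")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


@dataclass
class SimResult:
    """The four generated tables plus planted ground truth."""

    cohort: pd.DataFrame
    neuropsych: pd.DataFrame
    morphometry: pd.DataFrame
    icv: pd.Series
    findings: pd.DataFrame
    directions: dict
    truth: dict
    config: SimConfig

    @property
    def patients(self):
        return self.cohort.index[self.cohort["group"] == "patient"]

    @property
    def controls(self):
        return self.cohort.index[self.cohort["group"] == "control"]

    @property
    def outcome_grid(self) -> pd.DataFrame:
        cols = [c for c in self.cohort.columns if c.startswith("outcome_")]
        return self.cohort.loc[self.patients, cols]


def simulate_cohort(config: SimConfig | None = None) -> SimResult:
    """Draw one synthetic cohort. Deterministic given ``config.seed``."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence(int(cfg.seed)))

    ids = [f"C{i + 1:03d}" for i in range(cfg.n_controls)] \
        + [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    group = ["control"] * cfg.n_controls + ["patient"] * cfg.n_patients
    n_total = len(ids)
    is_patient = np.array([g == "patient" for g in group])

    # demographics
    lo, hi = cfg.age_range
    age = np.where(
        is_patient,
        rng.normal(cfg.patient_age[0], cfg.patient_age[1], n_total),
        rng.normal(cfg.control_age[0], cfg.control_age[1], n_total),
    ).clip(lo, hi)
    sex = np.where(rng.random(n_total) < cfg.male_prob, "male", "female")
    education = np.where(rng.random(n_total) < cfg.highschool_prob,
                         "completed-high-school", "not")

    cohort = pd.DataFrame({"group": group, "age": np.round(age, 2),
                           "sex": sex, "education": education},
                          index=pd.Index(ids, name="participant_id"))

    # neuropsychological features: common deficit factor + idiosyncratic noise
    features = list(NEUROPSYCH_DIRECTIONS)
    rho = cfg.feature_correlation
    factor = rng.normal(size=n_total)
    eps = rng.normal(size=(n_total, len(features)))
    deficit = np.sqrt(abs(rho)) * np.sign(rho) * factor[:, None] + np.sqrt(1 - abs(rho)) * eps
    neuro = {}
    for j, feat in enumerate(features):
        sign = 1.0 if NEUROPSYCH_DIRECTIONS[feat] == "higher_worse" else -1.0
        z = sign * deficit[:, j] + is_patient * cfg.feature_effects.get(feat, 0.0)
        mean, sd = FEATURE_SCALES[feat]
        neuro[feat] = mean + sd * z
    neuropsych = pd.DataFrame(neuro, index=cohort.index)
    if cfg.missing_rate > 0:
        mask = rng.random(neuropsych.shape) < cfg.missing_rate
        neuropsych = neuropsych.mask(mask)

    # morphometry: ICV depends on sex; volumes track ICV; mild age slope
    icv_mean = np.where(sex == "male", 1_550_000.0, 1_400_000.0)
    icv = pd.Series(rng.normal(icv_mean, 110_000.0), index=cohort.index,
                    name="EstimatedTotalIntraCranialVol")
    icv_std = (icv - icv.mean()) / icv.std(ddof=1)
    morph = {}
    for roi in THICKNESS_ROIS:
        base, sd = 2.5, 0.15
        vals = base + sd * rng.normal(size=n_total) - 0.004 * (age - 40.0)
        vals = vals + is_patient * cfg.region_effects.get(roi, 0.0) * sd
        morph[roi] = vals
    r_icv = 0.45
    for roi, (base, sd) in VOLUME_STRUCTURES.items():
        noise = rng.normal(size=n_total)
        vals = base + sd * (r_icv * icv_std.to_numpy()
                            + np.sqrt(1 - r_icv**2) * noise) - 0.002 * base / 10 * (age - 40.0)
        vals = vals + is_patient * cfg.region_effects.get(roi, 0.0) * sd
        morph[roi] = vals
    morphometry = pd.DataFrame(morph, index=cohort.index)

    # radiological findings: independent Bernoulli per (code, group)
    codes = sorted({code for code, _ in cfg.finding_prevalence})
    fdata = {}
    for code in codes:
        prob = np.where(is_patient,
                        cfg.finding_prevalence.get((code, "patient"), 0.0),
                        cfg.finding_prevalence.get((code, "control"), 0.0))
        fdata[code] = rng.random(n_total) < prob
    findings = pd.DataFrame(fdata, index=cohort.index)

    # seizure outcomes: first-order Markov chain, patients only
    tm = np.asarray(cfg.outcome_transition, dtype=float)
    states = np.empty((n_total, cfg.n_epochs), dtype=object)
    states[:] = None
    current = rng.random(n_total) < cfg.outcome_initial_sf  # True = SF
    for e in range(cfg.n_epochs):
        if e > 0:
            stay_sf = rng.random(n_total) < np.where(current, tm[0, 0], tm[1, 0])
            current = stay_sf
        states[:, e] = np.where(current, "SF", "PS")
    miss = rng.random((n_total, cfg.n_epochs)) < cfg.missing_rate
    for e in range(cfg.n_epochs):
        col = pd.Series(states[:, e], index=cohort.index, dtype=object)
        col[miss[:, e]] = pd.NA
        col[~is_patient] = pd.NA  # controls have no outcome follow-up
        cohort[f"outcome_{6 * (e + 1):02d}m"] = col

    truth = {
        "feature_effects": dict(cfg.feature_effects),
        "region_effects": dict(cfg.region_effects),
        "finding_prevalence": {f"{c}|{g}": p for (c, g), p in cfg.finding_prevalence.items()},
        "outcome_transition": np.asarray(cfg.outcome_transition).tolist(),
        "outcome_initial_sf": cfg.outcome_initial_sf,
        "missing_rate": cfg.missing_rate,
        "seed": cfg.seed,
    }
    return SimResult(cohort=cohort, neuropsych=neuropsych, morphometry=morphometry,
                     icv=icv, findings=findings,
                     directions=dict(NEUROPSYCH_DIRECTIONS), truth=truth, config=cfg)


def plant_profiles(config: SimConfig, k: int, profile_means, mixing=None,
                   features=None) -> tuple[pd.DataFrame, pd.Series]:
    """Draw patient feature vectors from a k-component Gaussian mixture.

    ``profile_means`` is k x features (z units); each patient is assigned
    to one component by ``mixing`` (defaults to uniform) and drawn with
    unit isotropic noise around the component mean. Returns the feature
    matrix and the true component labels (for recovery tests).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    means = np.atleast_2d(np.asarray(profile_means, dtype=float))
    if means.shape[0] != k:
        raise ValueError(f"profile_means has {means.shape[0]} rows, expected k={k}")
    p = means.shape[1]
    if features is None:
        features = list(NEUROPSYCH_DIRECTIONS)[:p]
    if len(features) != p:
        raise ValueError("features length must match profile_means columns")
    if mixing is None:
        mixing = np.full(k, 1.0 / k)
    mixing = np.asarray(mixing, dtype=float)
    if mixing.shape != (k,) or (mixing < 0).any() or not np.isclose(mixing.sum(), 1.0):
        raise ValueError("mixing must be k non-negative proportions summing to 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x9E3779B9]))
    n = config.n_patients
    labels = rng.choice(k, size=n, p=mixing)
    values = means[labels] + rng.normal(size=(n, p))
    ids = pd.Index([f"P{i + 1:03d}" for i in range(n)], name="participant_id")
    return (pd.DataFrame(values, index=ids, columns=features),
            pd.Series(labels, index=ids, name="true_profile"))


def example_profile_means(scale: float = 2.0) -> pd.DataFrame:
    """Four reference patient profiles for cluster-recovery studies.

    The profiles sit at the vertices of a regular simplex in the
    3-dimensional subspace spanned by a mood-symptom axis (depression,
    anxiety), a sensorimotor-deficit axis (reaction time up, finger
    tapping down), and a cognitive-deficit axis (the seven memory /
    working-memory / speed / executive indices down), so every pair of
    profiles is equally distinct (pairwise separation ``2 * sqrt(2) *
    scale`` SD; 5.66 SD at the default). Two profiles load positively on
    mood symptoms, mirroring the mood-dominant and globally-impaired
    patient phenotypes; the others are mood-quiet. Equidistance makes the
    elbow of the WCSS curve unambiguous at k = 4.
    """
    features = list(NEUROPSYCH_DIRECTIONS)
    u_mood = np.zeros(len(features))
    u_mood[[features.index("Depression PHQ9"), features.index("Anxiety GAD7")]] = 1 / np.sqrt(2)
    u_motor = np.zeros(len(features))
    u_motor[[features.index("Visual RT M"), features.index("Visual RT SD")]] = 0.5
    u_motor[[features.index("Finger Tapping RH"), features.index("Finger Tapping LH")]] = -0.5
    u_cog = np.zeros(len(features))
    cog = ["Auditory Memory", "Delayed Memory", "Immediate Memory", "Visual Memory",
           "Working Memory", "Processing Speed", "Executive Function"]
    u_cog[[features.index(f) for f in cog]] = -1 / np.sqrt(len(cog))
    verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    means = scale * (verts @ np.vstack([u_mood, u_motor, u_cog]))
    return pd.DataFrame(means, index=[f"profile_{i + 1}" for i in range(4)], columns=features)


def write_tables(result: SimResult, outdir) -> dict[str, Path]:
    """Write the four tables as UTF-8 TSV plus a JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", na_rep="NA", encoding="utf-8")
        paths[name] = path

    _write(result.cohort, "cohort")
    _write(result.neuropsych, "neuropsych")
    morph = pd.concat([result.morphometry, result.icv], axis=1)
    _write(morph, "morphometry")
    _write(result.findings.astype(int), "findings")
    sidecar = outdir / "truth.json"
    sidecar.write_text(json.dumps(result.truth, indent=2, sort_keys=True))
    paths["truth"] = sidecar
    return paths
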