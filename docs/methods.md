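# Methods

This note documents the statistical procedures implemented in `epinorm`,
the choices made where the design was genuinely open, and what the
bundled synthetic-data generator does and does not emulate.

## Resampling normative z-scores

For participant *i* and feature *f*, the normative z-score is

> z(i, f) = (x(i, f) − c(i, f)) / s(i, f)

where c is the mean over B control subsamples of the subsample mean, and
s the mean over the same B subsamples of the subsample SD. Each
subsample draws m distinct controls without replacement; the B subsamples
are mutually independent. Defaults: **B = 100**, **m = 10**, SD with the
n−1 denominator (configurable to n). When the scored participant is a
control, their own row is excluded from every subsample, so a control's z
never reflects their own value.

Properties and consequences:

* **Conservative scale.** E[s] is the expected SD of a 10-observation
  sample, which is below the population SD for Gaussian data
  (c₄(10) ≈ 0.973) but is averaged over subsamples whose SDs vary; the
  net effect is a z-scale close to, but not identical to, naive
  standardization. Control z-scores therefore have mean ≈ 0 and SD
  slightly different from 1; the test suite asserts SD within ±10%.
* **Exact oracle.** For small control pools the estimator has a closed
  enumeration: `enumerate_normative` averages over all C(n, m) subsets
  (capped at 10⁶ subsets). The sampled estimator converges to it as B
  grows; at B = 10⁴ the agreement is within 1% (asserted).
* **Reproducibility.** The random stream for each (participant, feature)
  pair is derived deterministically from (seed, participant id, feature
  name) via CRC32-keyed `SeedSequence`s. Results are therefore invariant
  to row/column order and to which other participants are scored in the
  same call.
* **Degenerate features.** If the eligible-control pool for a feature is
  smaller than m, or the averaged subsample SD is 0 (all controls equal),
  the z is set missing and the feature is reported in
  `degenerate_features` with a logged warning. Missing control values are
  dropped before subsampling; fitting requires at least m + 1 non-missing
  controls per feature so leave-self-out remains possible.

## Abnormality flags

Each feature declares a direction: `higher_worse` (depression PHQ-9,
anxiety GAD-7, visual reaction time mean and SD) or `lower_worse` (the
nine performance indices). The flag rule at threshold T is `z > T` for
higher-worse and `z < −T` for lower-worse features, with **strict**
inequalities. The lower-worse rule is a deviation *magnitude* beyond T SD
below the normative centre: reading the threshold as a literal `z < +2`
would flag ~98% of any Gaussian population, which contradicts the
single-digit control prevalences such rules produce in practice. T = 2
is the primary clinical convention; T = 1 is carried as a first-class
ancillary threshold. Flags are missing wherever z is missing; prevalence
percentages are computed over non-missing flags and group differences
use the uncorrected Pearson chi-square.

## Cognitive profiles

Patient z-scores are median-imputed per feature (the imputation is
logged), standardized to mean 0 / SD 1 (n−1 denominator; zero-variance
columns are dropped with a warning), and clustered with Lloyd's k-means,
best of **n_init = 25** restarts, convergence tolerance 10⁻⁶. The WCSS
curve is scanned over k = 1..8 by default; the automated elbow
suggestion is the k maximizing the second difference of the curve. The
final k can be pinned in the configuration — the conventional workflow
combines the elbow with visual inspection of cluster overlap in PCA
space, which cannot be automated; both the suggestion and the chosen k
are recorded in the manifest. Cluster labels are stabilized by
decreasing cluster size with a lexicographic centroid tie-break, so
reports are identical across reruns. Profile summaries report the mean
*raw* z per (cluster, feature) plus cluster sizes.

## Regional morphometry statistics

Per ROI, ordinary least squares: `measure ~ group + age + sex + ICV`,
with group coded 0 = control, 1 = patient. The covariate-adjusted effect
size is **d = t·√(1/n₁ + 1/n₂)** from the group t-statistic — the
standard conversion for an adjusted comparison, and exactly testable
against t. ICV is included for thickness and volume models alike;
regressions across ROIs share the design matrix and are solved with a
vectorized least-squares path (verified against `statsmodels.OLS` in the
test suite). Benjamini–Hochberg FDR is applied separately within each
measure family (thickness; volume), mirroring per-analysis correction.
Rows with missing covariates are dropped and logged; a singular design
raises an error naming the ROI.

The **negative-deviation burden** is, per participant, 100 × (number of
ROIs with z < 0) / (number of non-missing ROIs), using the same
resampling z procedure as neuropsychology (the study defines exactly one
z construction). Only the sign of z enters, so the burden is invariant
to any strictly monotone sign-preserving per-ROI transform. The burden
is regressed on group with the same covariates via `statsmodels` OLS;
the report carries the group coefficient in percentage points with 95%
CI, t, residual df, p, the intercept (control-referenced level) with CI,
and R². Morphology–cognition association uses pairwise Pearson
correlations (≥ 4 overlapping patients per pair, constant vectors
skipped and logged) with BH-FDR across all pairs.

## Generic tests

* Pearson chi-square **without Yates continuity correction** — the
  uncorrected statistic is what standard clinical summary-table engines
  compute, and is the variant that reproduces published table p-values
  from published counts (verified in the acceptance suite).
* One-way ANOVA from raw data (`scipy.stats.f_oneway`) and from
  per-group (n, mean, SD) summaries; the two are algebraically identical
  under matching moments (asserted to 10⁻¹⁰). Two-group comparisons stay
  ANOVA-shaped; the F = t² identity is asserted rather than substituting
  a t-test.
* Cochran–Armitage linear trend for 2 × k ordered tables with
  unit-spaced scores by default; implemented directly (the statistic has
  no direct scipy/statsmodels counterpart) and cross-checked against the
  statsmodels linear-by-linear association z-score, from which it
  differs only by the (N−1)/N variance convention, and against a
  label-permutation oracle.
* Benjamini–Hochberg step-up q-values via
  `statsmodels.stats.multitest.multipletests`.

## Findings taxonomy

The shipped vocabulary maps every finding code to exactly one of
`epilepsy_related`, `unknown`, or `incidental`. A participant's overall
MRI conclusion is *abnormal* iff they carry any epilepsy-related or
unknown-category finding; incidental-only participants conclude normal.
Categories are **non-exclusive** at the participant level — one person
can contribute to several categories, so category percentages need not
sum to 100 (participant-level category prevalence and per-code
prevalence are both reported, as the two can differ when one participant
carries several codes of a category). Supratentorial arachnoid cysts
default to `unknown` and can be re-categorized per participant (e.g.
after EEG localizes seizures elsewhere) through the `overrides`
mechanism.

Outcome grids hold one label per 6-month epoch in {SF, PS, missing}.
Per-epoch seizure-freedom proportions use non-missing labels only;
consistency classes (always-SF / always-PS / mixed) are judged on
observed epochs only and partition the patients with at least one
observed epoch.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
with all parameters declared in `SimConfig`:

* **Cohort**: 104 patients / 45 controls by default; ages Gaussian
  (patients 35.8 ± 13.5, controls 40.8 ± 15.7, truncated to 16–70),
  ~54% male, ~60% completed high school.
* **Neuropsychology**: multivariate Gaussian with a single common
  "deficit" factor (pairwise correlation 0.3) sign-aligned with each
  feature's worse direction, de-standardized to plausible raw scales.
  Patient shifts (`feature_effects`, control-SD units) default to values
  calibrated once through the Gaussian tail so that *expected* >2 SD
  flag rates match prevalences reported in newly diagnosed focal
  epilepsy (≈49% depression, ≈54% anxiety, ≈18% executive function, …):
  depression +2.0, anxiety +2.1, reaction-time mean +1.05, executive
  −1.09, processing speed −0.85, and so on. Realized single-cohort rates
  fluctuate around these targets because the 45-control reference mean
  itself carries ≈0.15 SD of sampling noise.
* **Morphometry**: 68 Desikan thickness ROIs (2.5 ± 0.15 mm, age slope
  −0.004 mm/yr) and 16 subcortical/cerebellar volumes with an ICV
  association (r ≈ 0.45) and a mild age slope; ICV is sex-dependent
  (males ≈ 1.55 L, females ≈ 1.40 L). Default planted effect: −0.4 SD
  thinning in 8 frontal ROIs — a moderate effect size matching adjusted
  t-statistics of ≈2–2.5 at these group sizes.
* **Findings**: independent Bernoulli draws per (code, group) with
  default prevalences typical of research-grade 3 T readings (e.g.
  white-matter hyperintensities 39% patients / 24% controls).
* **Outcomes**: first-order Markov chain over 6-month epochs, initial
  seizure-freedom probability 0.567, transitions SF→SF 0.85 and
  PS→SF 0.25 — parameters chosen to reproduce observed per-epoch
  seizure-freedom percentages (~57→62%) and the instability of epoch
  outcomes (roughly a third of patients consistently seizure-free, a
  quarter consistently not).
* **Missingness**: one element-wise rate (default 0.10) applied to
  neuropsychological entries and outcome epochs. Real follow-up
  missingness grows with epoch (≈10% → 50% over two years); a single
  rate keeps the configuration to one interpretable knob and is the main
  structural simplification of the outcome model.

What passing tests on this generator do **not** show: robustness to
non-Gaussian score distributions (raw neuropsychological scales are
bounded and often skewed), to spatially correlated morphometric noise
(real cortical thickness has strong inter-regional covariance), to
informative missingness, or to finding co-occurrence (real lesion codes
are correlated within participants). The generator is a correctness
harness, not a realism claim.

`plant_profiles` draws patients from a k-component Gaussian mixture with
unit isotropic noise and returns the true labels for recovery tests.
`example_profile_means()` provides four reference profiles at the
vertices of a regular simplex in the subspace spanned by a mood-symptom
axis, a sensorimotor-deficit axis, and a cognitive-deficit axis
(pairwise separation 5.66 SD at the default scale). Equidistance is
deliberate: the max-second-difference elbow rule identifies the true k
only when the k−1 merge costs are comparable, i.e. when profiles are
comparably distinct; with one dominant split the rule correctly reports
that two clusters explain most structure. Two of the four reference
profiles load positively on mood symptoms, echoing the mood-dominant and
globally-impaired phenotypes described in cognitive phenotyping studies.

## Numerical choices and problem sizes

* Enumeration oracle cap: 10⁶ subsets. Frozen oracle for controls
  {0..19}, m = 10: centre 9.5, scale 5.8756647057.
* k-means: Lloyd, tolerance 10⁻⁶, 25 restarts; empty clusters are
  handled by scikit-learn's re-seeding.
* The calibration studies in the test and acceptance suites use: 200
  simulated cohorts for the control-z centring check (30 controls each),
  B = 10⁴ for oracle agreement, 100 seeded cohorts (n = 104) for
  cluster recovery, 200 null plus 200 planted-effect simulations
  (104/45, 84 regions) for the regional-OLS calibration, and 1000 random
  z-matrices for the flag property sweep. These sizes put Monte-Carlo
  error well inside each assertion's tolerance.
* Under the complete null with independent tests, BH attains
  E[FDP] = q exactly, so the null-calibration assertion allows the
  one-sided Monte-Carlo error of that boundary value at 200 simulations.

## Known limitations

* The burden regression reports the intercept at covariate value zero
  (as standard OLS output); centre covariates first if a
  control-at-mean-covariates reading is wanted.
* The elbow rule is a heuristic; for continuous (non-clustered) data it
  tends to suggest k = 2. The chosen k should be confirmed against the
  PCA overlap plot, which is why the configuration carries an explicit
  `k` override.
* Trend-test p-values are asymptotic (normal); for very small tables an
  exact/permutation approach is preferable (the test suite demonstrates
  one).
* The taxonomy supports per-participant category overrides but not
  per-code probability models; findings are treated as given codes, not
  inferred readings.
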