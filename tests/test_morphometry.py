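"""Regional OLS group statistics, negative-z burden, and correlations."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import epinorm
from epinorm.morphometry import (morph_neuro_correlations, negative_z_burden,
                                 region_group_stats)


@pytest.fixture(scope="module")
def sim():
    return epinorm.simulate_cohort(epinorm.SimConfig(seed=42))


@pytest.fixture(scope="module")
def region_stats(sim):
    return region_group_stats(sim.morphometry, sim.cohort, sim.icv)


class TestRegionStats:
    def test_matches_statsmodels_per_roi(self, sim, region_stats):
        """The vectorized OLS agrees with a statsmodels fit on single ROIs."""
        for roi in ["lh_superiorfrontal_thickness", "Left-Hippocampus"]:
            df = pd.DataFrame({
                "y": sim.morphometry[roi],
                "group": (sim.cohort["group"] == "patient").astype(float),
                "age": sim.cohort["age"],
                "sex": (sim.cohort["sex"] == "male").astype(float),
                "icv": sim.icv,
            })
            fit = sm.OLS(df["y"], sm.add_constant(df[["group", "age", "sex", "icv"]])).fit()
            row = region_stats.loc[roi]
            assert row["beta"] == pytest.approx(fit.params["group"])
            assert row["t"] == pytest.approx(fit.tvalues["group"])
            assert row["p"] == pytest.approx(fit.pvalues["group"])

    def test_d_t_identity(self, sim, region_stats):
        n1 = (sim.cohort["group"] == "patient").sum()
        n0 = (sim.cohort["group"] == "control").sum()
        factor = np.sqrt(1 / n0 + 1 / n1)
        assert region_stats["d"].to_numpy() == pytest.approx(
            (region_stats["t"] * factor).to_numpy())

    def test_q_dominates_p_and_signs_agree(self, region_stats):
        assert (region_stats["q"] >= region_stats["p"] - 1e-12).all()
        nz = region_stats[region_stats["t"] != 0]
        assert (np.sign(nz["d"]) == np.sign(nz["t"])).all()

    def test_group_recode_antisymmetry(self, sim):
        flipped = sim.cohort.copy()
        flipped["group"] = flipped["group"].map({"patient": "control", "control": "patient"})
        a = region_group_stats(sim.morphometry, sim.cohort, sim.icv)
        b = region_group_stats(sim.morphometry, flipped, sim.icv)
        assert b["beta"].to_numpy() == pytest.approx(-a["beta"].to_numpy())
        assert b["t"].to_numpy() == pytest.approx(-a["t"].to_numpy())
        assert b["d"].to_numpy() == pytest.approx(-a["d"].to_numpy())
        assert b["p"].to_numpy() == pytest.approx(a["p"].to_numpy())

    def test_collinear_covariates_rejected(self, sim):
        cohort = sim.cohort.copy()
        cohort["age"] = 50.0  # constant, collinear with the intercept
        with pytest.raises(ValueError, match="singular"):
            region_group_stats(sim.morphometry.iloc[:, :3], cohort, sim.icv)

    def test_measure_families(self, region_stats):
        assert region_stats.loc["lh_precentral_thickness", "measure"] == "thickness"
        assert region_stats.loc["Left-Thalamus", "measure"] == "volume"


class TestBurden:
    def test_all_positive_z_gives_zero_burden(self, sim):
        z = pd.DataFrame(np.ones((len(sim.cohort), 5)), index=sim.cohort.index)
        res = negative_z_burden(z, sim.cohort, sim.icv)
        assert (res.burden == 0).all()

    def test_burden_counts_negative_fraction(self, sim):
        z = pd.DataFrame(
            [[-1.0, 1.0, -2.0, np.nan]] * len(sim.cohort), index=sim.cohort.index)
        res = negative_z_burden(z, sim.cohort, sim.icv)
        assert res.burden.iloc[0] == pytest.approx(100 * 2 / 3)

    def test_monotone_transform_invariance(self, sim, rng):
        z = pd.DataFrame(rng.normal(size=(len(sim.cohort), 8)), index=sim.cohort.index)
        a = negative_z_burden(z, sim.cohort, sim.icv)
        transformed = np.sign(z) * np.expm1(np.abs(z))  # strictly monotone, sign-preserving
        b = negative_z_burden(transformed, sim.cohort, sim.icv)
        pd.testing.assert_series_equal(a.burden, b.burden)
        assert b.beta == pytest.approx(a.beta)

    def test_all_missing_participant_excluded(self, sim):
        z = pd.DataFrame(rng_z := np.random.default_rng(0).normal(
            size=(len(sim.cohort), 4)), index=sim.cohort.index)
        z.iloc[0] = np.nan
        res = negative_z_burden(z, sim.cohort, sim.icv)
        assert sim.cohort.index[0] not in res.burden.index

    def test_ci_brackets_beta_and_burden_bounded(self, sim):
        zm = epinorm.normative_z(sim.morphometry.iloc[:, :12], sim.controls,
                                 epinorm.ResamplingSpec(seed=1))
        res = negative_z_burden(zm, sim.cohort, sim.icv)
        assert res.conf_int[0] <= res.beta <= res.conf_int[1]
        assert res.burden.between(0, 100).all()
        assert res.df == len(res.burden) - 5

    def test_null_simulation_covers_zero(self):
        """Group beta CI covers 0 in ~95% of null simulations (quick check)."""
        cover = 0
        n_sims = 40
        for seed in range(n_sims):
            sim = epinorm.simulate_cohort(epinorm.SimConfig(
                n_patients=60, n_controls=30, seed=seed,
                feature_effects={}, region_effects={}, missing_rate=0.0))
            rng = np.random.default_rng(seed + 1000)
            z = pd.DataFrame(rng.normal(size=(90, 20)), index=sim.cohort.index)
            res = negative_z_burden(z, sim.cohort, sim.icv)
            cover += res.conf_int[0] <= 0 <= res.conf_int[1]
        assert cover / n_sims >= 0.85


class TestCorrelations:
    def test_identical_vectors_give_r_one(self, sim):
        morph = sim.morphometry.iloc[:, :2]
        z = morph.iloc[:, [0]].rename(columns={morph.columns[0]: "feat"})
        out = morph_neuro_correlations(morph, z, sim.patients)
        row = out[(out["roi"] == morph.columns[0]) & (out["feature"] == "feat")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-12

    def test_negation_flips_r(self, sim, rng):
        morph = sim.morphometry.iloc[:, :3]
        z = pd.DataFrame({"feat": rng.normal(size=len(morph))}, index=morph.index)
        a = morph_neuro_correlations(morph, z, sim.patients)
        b = morph_neuro_correlations(morph, -z, sim.patients)
        assert b["r"].to_numpy() == pytest.approx(-a["r"].to_numpy())

    def test_constant_vector_skipped(self, sim):
        morph = sim.morphometry.iloc[:, :2].copy()
        z = pd.DataFrame({"feat": np.ones(len(morph))}, index=morph.index)
        out = morph_neuro_correlations(morph, z, sim.patients)
        assert out.empty

    def test_independent_pair_has_small_r(self):
        """|r| < 0.2 in >= 95% of null draws at n = 104."""
        rng = np.random.default_rng(7)
        small = 0
        n_sims = 200
        for _ in range(n_sims):
            a, b = rng.normal(size=(2, 104))
            small += abs(np.corrcoef(a, b)[0, 1]) < 0.2
        assert small / n_sims >= 0.95
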