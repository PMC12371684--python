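"""Finding taxonomy, prevalence reports, cohort summary, outcome grids."""

import numpy as np
import pandas as pd
import pytest

from epinorm.findings import (VOCABULARY, category_prevalence, cohort_summary,
                              conclusions, outcome_tabulation)


def _cohort(n_control, n_patient):
    ids = [f"c{i}" for i in range(n_control)] + [f"p{i}" for i in range(n_patient)]
    return pd.DataFrame({"group": ["control"] * n_control + ["patient"] * n_patient},
                        index=ids)


def _findings(index, **cols):
    df = pd.DataFrame(False, index=index, columns=sorted(VOCABULARY))
    for code, ids in cols.items():
        df.loc[list(ids), code] = True
    return df


class TestConclusions:
    def test_vocabulary_covers_all_three_categories(self):
        cats = {fc.category for fc in VOCABULARY.values()}
        assert cats == {"epilepsy_related", "unknown", "incidental"}
        assert "unknown_arachnoid_cyst" in VOCABULARY
        assert VOCABULARY["unknown_arachnoid_cyst"].category == "unknown"

    def test_epilepsy_or_unknown_concludes_abnormal(self):
        cohort = _cohort(0, 3)
        f = _findings(cohort.index,
                      epilepsy_mcd=["p0"],
                      unknown_white_matter_hyperintensities=["p1"])
        c = conclusions(f)
        assert c.loc["p0"] == "abnormal"
        assert c.loc["p1"] == "abnormal"
        assert c.loc["p2"] == "normal"

    def test_incidental_only_concludes_normal(self):
        cohort = _cohort(0, 1)
        f = _findings(cohort.index, incidental_single_lesion=["p0"])
        assert conclusions(f).loc["p0"] == "normal"

    def test_unknown_code_flip_never_clears_abnormal(self, rng):
        """Adding an unknown-category finding can only make things abnormal."""
        cohort = _cohort(0, 20)
        f = pd.DataFrame(rng.random((20, len(VOCABULARY))) < 0.2,
                         index=cohort.index, columns=sorted(VOCABULARY))
        before = conclusions(f)
        unknown_codes = [c for c, fc in VOCABULARY.items() if fc.category == "unknown"]
        for pid in cohort.index[:5]:
            for code in unknown_codes[:3]:
                g = f.copy()
                g.loc[pid, code] = True
                after = conclusions(g)
                if before.loc[pid] == "abnormal":
                    assert after.loc[pid] == "abnormal"

    def test_override_reclassifies_arachnoid_cyst(self):
        cohort = _cohort(0, 1)
        f = _findings(cohort.index, unknown_arachnoid_cyst=["p0"])
        assert conclusions(f).loc["p0"] == "abnormal"
        over = {("p0", "unknown_arachnoid_cyst"): "incidental"}
        assert conclusions(f, overrides=over).loc["p0"] == "normal"

    def test_unknown_code_rejected(self):
        f = pd.DataFrame({"flying_saucer": [True]}, index=["p0"])
        with pytest.raises(KeyError, match="flying_saucer"):
            conclusions(f)


class TestCategoryPrevalence:
    def test_counts_once_per_category_and_overlap(self):
        cohort = _cohort(2, 4)
        f = _findings(cohort.index,
                      unknown_single_lesion=["p0", "p1"],
                      unknown_multiple_lesions=["p0"],          # same category, same person
                      epilepsy_cavernoma=["p0"],                # second category
                      incidental_single_lesion=["c0"])
        rep = category_prevalence(f, cohort)
        cats = rep["categories"]
        assert cats.loc["unknown", "patient_n"] == 2          # p0 counted once
        assert cats.loc["epilepsy_related", "patient_n"] == 1
        assert cats.loc["incidental", "control_n"] == 1
        assert cats.loc["unknown", "patient_pct"] == pytest.approx(50.0)
        # overlap: category percentages may exceed 100 in total
        assert cats.loc["abnormal_conclusion", "patient_n"] == 2
        assert cats.loc["normal_conclusion", "control_n"] == 2

    def test_per_code_counts(self):
        cohort = _cohort(2, 4)
        f = _findings(cohort.index, unknown_single_lesion=["p0", "p1", "c0"])
        codes = category_prevalence(f, cohort)["codes"]
        assert codes.loc["unknown_single_lesion", "patient_n"] == 2
        assert codes.loc["unknown_single_lesion", "control_pct"] == pytest.approx(50.0)

    def test_empty_findings_all_normal(self):
        cohort = _cohort(3, 3)
        f = _findings(cohort.index)
        rep = category_prevalence(f, cohort)
        assert (rep["categories"].loc["normal_conclusion",
                                      ["control_pct", "patient_pct"]] == 100.0).all()
        for cat in ("epilepsy_related", "unknown", "incidental"):
            assert rep["categories"].loc[cat, "patient_n"] == 0


class TestCohortSummary:
    def test_continuous_summary_matches_direct_computation(self):
        cohort = _cohort(3, 3)
        cohort["age"] = [30.0, 40.0, 50.0, 20.0, 30.0, 40.0]
        out = cohort_summary(cohort, {"age": "continuous"})
        assert out.loc[0, "control_summary"] == "40.000 (10.000)"
        assert out.loc[0, "patient_summary"] == "30.000 (10.000)"

    def test_sex_table_reproduces_published_p(self):
        """2x2 sex counts (24/21 vs 57/47) give the published p = .868."""
        cohort = _cohort(45, 104)
        cohort["sex"] = (["male"] * 24 + ["female"] * 21
                         + ["male"] * 57 + ["female"] * 47)
        out = cohort_summary(cohort, {"sex": "categorical"})
        p = out["p"].dropna().iloc[0]
        assert round(p, 3) == 0.868

    def test_all_missing_variable_reports_nmiss_without_test(self):
        cohort = _cohort(2, 2)
        cohort["phantom"] = np.nan
        out = cohort_summary(cohort, {"phantom": "continuous"})
        assert out.loc[0, "n_miss"] == 4
        assert np.isnan(out.loc[0, "p"])

    def test_ordered_variable_uses_trend_test(self):
        cohort = _cohort(30, 30)
        lv = pd.Categorical(["low"] * 20 + ["mid"] * 7 + ["high"] * 3
                            + ["low"] * 5 + ["mid"] * 10 + ["high"] * 15,
                            categories=["low", "mid", "high"], ordered=True)
        cohort["stage"] = lv
        out = cohort_summary(cohort, {"stage": "ordered"})
        assert out["p"].dropna().iloc[0] < 0.01

    def test_untyped_variable_rejected(self):
        cohort = _cohort(2, 2)
        cohort["x"] = 1.0
        with pytest.raises(ValueError, match="type"):
            cohort_summary(cohort, {"x": "mystery"})


class TestOutcomeTabulation:
    def test_hand_worked_three_patient_grid(self):
        grid = pd.DataFrame([["SF", "PS"], ["SF", "SF"], [np.nan, "PS"]],
                            columns=["e1", "e2"], index=["a", "b", "c"])
        out = outcome_tabulation(grid)
        assert out.per_epoch.loc["e1", "sf_pct"] == pytest.approx(100.0)
        assert out.per_epoch.loc["e2", "sf_pct"] == pytest.approx(100 / 3)
        assert out.always_sf_pct == pytest.approx(100 / 3)
        assert out.always_ps_pct == pytest.approx(100 / 3)
        assert out.mixed_pct == pytest.approx(100 / 3)

    def test_all_seizure_free(self):
        grid = pd.DataFrame([["SF", "SF"]] * 4, columns=["e1", "e2"])
        out = outcome_tabulation(grid)
        assert out.always_sf_pct == pytest.approx(100.0)
        assert out.mixed_pct == pytest.approx(0.0)

    def test_consistency_classes_partition(self, default_sim):
        out = outcome_tabulation(default_sim.outcome_grid)
        assert out.always_sf_pct + out.always_ps_pct + out.mixed_pct \
            == pytest.approx(100.0)

    def test_row_permutation_invariance(self, default_sim):
        grid = default_sim.outcome_grid
        a = outcome_tabulation(grid)
        b = outcome_tabulation(grid.sample(frac=1, random_state=3))
        pd.testing.assert_frame_equal(a.per_epoch, b.per_epoch)
        assert a.counts == b.counts

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="epoch"):
            outcome_tabulation(pd.DataFrame(index=["a"]))
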