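"""Resampling normative z-scores against the exhaustive-enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

import epinorm
from epinorm.normative import (NormativeZScorer, ResamplingSpec,
                               enumerate_normative, normative_z)

# frozen oracle values for controls {0..19}, m=10: mean over all C(20,10)
# subsamples of the subsample mean, and of the subsample SD (ddof=1)
ORACLE_CENTRE = 9.5
ORACLE_SCALE = 5.8756647057
ORACLE_Z_215 = 2.0423221203


def _frame(control_values, subjects=None, feature="f"):
    vals = list(control_values) + list(subjects or [])
    ids = [f"c{i}" for i in range(len(control_values))] \
        + [f"s{i}" for i in range(len(subjects or []))]
    return pd.DataFrame({feature: vals}, index=ids), [f"c{i}" for i in range(len(control_values))]


class TestEnumeration:
    def test_full_pool_subsample_is_plain_moments(self):
        vals = [1.0, 4.0, 7.0, 9.0, 12.0]
        centre, scale = enumerate_normative(vals, m=len(vals))
        assert centre == pytest.approx(np.mean(vals))
        assert scale == pytest.approx(np.std(vals, ddof=1))

    def test_singleton_subsample_sd_undefined(self):
        with pytest.raises(ValueError, match="ingleton"):
            enumerate_normative([1.0, 2.0, 3.0], m=1)

    def test_symmetric_pool_centre(self):
        centre, scale = enumerate_normative(np.arange(20.0), m=10)
        assert centre == pytest.approx(ORACLE_CENTRE)
        assert scale == pytest.approx(ORACLE_SCALE, abs=1e-8)

    def test_cap_exceeded(self):
        with pytest.raises(ValueError, match="cap"):
            enumerate_normative(np.arange(40.0), m=20, cap=1000)


class TestNormativeZ:
    def test_sampled_z_matches_enumeration(self):
        """B=100 z for score 21.5 vs controls {0..19} is within 0.1 of the oracle."""
        scores, controls = _frame(np.arange(20.0), subjects=[21.5])
        for seed in (0, 1, 42):
            zm = normative_z(scores, controls, ResamplingSpec(n_resamples=100,
                                                              subsample_size=10, seed=seed))
            assert zm.z.loc["s0", "f"] == pytest.approx(ORACLE_Z_215, abs=0.1)

    def test_score_at_centre_gives_near_zero_z(self):
        scores, controls = _frame(np.arange(20.0), subjects=[9.5])
        zm = normative_z(scores, controls, ResamplingSpec(seed=3))
        # centre is an average of subsample means whose expectation is 9.5
        assert zm.z.loc["s0", "f"] == pytest.approx(0.0, abs=0.1)

    def test_all_equal_controls_are_degenerate(self):
        scores, controls = _frame([5.0] * 12, subjects=[5.0])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            zm = normative_z(scores, controls, ResamplingSpec(subsample_size=4))
        assert np.isnan(zm.z.loc["s0", "f"])
        assert "f" in zm.degenerate_features

    def test_nearly_equal_controls_are_defined(self):
        scores, controls = _frame([5.0] * 11 + [6.0], subjects=[5.0])
        zm = normative_z(scores, controls, ResamplingSpec(subsample_size=4, seed=0))
        assert np.isfinite(zm.z.loc["s0", "f"])

    def test_missing_score_gives_missing_z(self):
        scores, controls = _frame(np.arange(15.0), subjects=[np.nan])
        zm = normative_z(scores, controls, ResamplingSpec(subsample_size=5))
        assert np.isnan(zm.z.loc["s0", "f"])

    def test_location_scale_equivariance(self):
        """x -> a*x + b leaves every z identical (same seed streams)."""
        rng = np.random.default_rng(5)
        scores, controls = _frame(rng.normal(50, 8, 25), subjects=[61.0, 38.5])
        spec = ResamplingSpec(seed=11)
        z0 = normative_z(scores, controls, spec).z
        z1 = normative_z(scores * 3.5 + 12.0, controls, spec).z
        pd.testing.assert_frame_equal(z0, z1)

    def test_leave_self_out(self):
        """A control's z is identical whether or not their row is in the pool."""
        rng = np.random.default_rng(8)
        scores, controls = _frame(rng.normal(size=20))
        spec = ResamplingSpec(subsample_size=8, seed=2)
        z_all = normative_z(scores, controls, spec).z
        # score c0 as an outside subject against the other 19 controls
        others = [c for c in controls if c != "c0"]
        z_ext = normative_z(scores, others, spec).z
        assert z_all.loc["c0", "f"] == pytest.approx(z_ext.loc["c0", "f"])

    def test_order_independence(self):
        rng = np.random.default_rng(9)
        scores, controls = _frame(rng.normal(size=18), subjects=[1.2, -0.5])
        spec = ResamplingSpec(subsample_size=6, seed=4)
        z0 = normative_z(scores, controls, spec).z
        shuffled = scores.sample(frac=1, random_state=1)
        z1 = normative_z(shuffled, controls, spec).z
        pd.testing.assert_frame_equal(z0, z1.loc[z0.index])

    def test_control_group_z_is_standardized(self):
        """Control z has mean ~0 and SD within 10% of 1 on a simulated cohort."""
        rng = np.random.default_rng(77)
        n = 200
        scores = pd.DataFrame({"f": rng.normal(10, 2, n)},
                              index=[f"c{i}" for i in range(n)])
        zm = normative_z(scores, scores.index, ResamplingSpec(seed=0))
        zc = zm.z["f"]
        assert abs(zc.mean()) < 0.1
        assert 0.9 < zc.std(ddof=1) < 1.1

    def test_insufficient_controls_rejected(self):
        scores, controls = _frame(np.arange(10.0))
        with pytest.raises(ValueError, match="non-missing"):
            normative_z(scores, controls, ResamplingSpec(subsample_size=10))


class TestScorerEstimator:
    def test_sklearn_param_round_trip(self):
        scorer = NormativeZScorer(n_resamples=50, subsample_size=5, seed=9)
        params = scorer.get_params()
        clone = NormativeZScorer(**params)
        assert clone.get_params() == params

    def test_transform_requires_fit(self):
        with pytest.raises(ValueError, match="not fitted"):
            NormativeZScorer().transform(pd.DataFrame({"f": [1.0]}))

    def test_unseen_feature_rejected(self):
        scores, controls = _frame(np.arange(15.0))
        scorer = NormativeZScorer(subsample_size=5).fit(scores.loc[controls])
        with pytest.raises(ValueError, match="not seen"):
            scorer.transform(pd.DataFrame({"other": [1.0]}, index=["x"]))
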