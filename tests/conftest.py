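import numpy as np
import pandas as pd
import pytest

import epinorm


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cohort (104 patients / 45 controls), seed 0."""
    return epinorm.simulate_cohort(epinorm.SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast cohort for pipeline-level tests."""
    cfg = epinorm.SimConfig(n_patients=40, n_controls=20, seed=7)
    return epinorm.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_z():
    """A hand-sized z matrix with one missing entry."""
    return pd.DataFrame(
        {
            "Depression PHQ9": [0.5, 2.5, -1.0, np.nan],
            "Executive Function": [-2.5, 0.0, 2.0, -1.5],
        },
        index=["p1", "p2", "p3", "p4"],
    )
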