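import numpy as np
import pytest

from metacog import CohortDesign, ObserverModel, StaircaseConfig, generate_cohort
from metacog.cohort import generate_item_weights


@pytest.fixture(scope="session")
def weights():
    return generate_item_weights(0)


@pytest.fixture(scope="session")
def observer():
    """Calibrated observer whose staircase equilibrium sits mid-range."""
    return ObserverModel(sigma=6.7)


@pytest.fixture(scope="session")
def small_design():
    """A miniature three-arm design for fast integration tests."""
    return CohortDesign(
        seed=20,
        n_per_arm={"icbt": 12, "antidepressant": 6, "control": 6},
        staircase=StaircaseConfig(n_trials=30, n_blocks=5),
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return generate_cohort(small_design)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
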