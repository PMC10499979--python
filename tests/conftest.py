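import numpy as np
import pytest

from stonemesh.cohort_validation import phantom_predictor_pool
from stonemesh.phantom_sim import sample_cohort_phantoms

# the eight-level staghorn worked through in the clinical illustration:
# raw orthogonal (x, y) measurements in mm, top to bottom
WORKED_EXAMPLE_MM = [
    (22.63, 18.08),
    (19.73, 19.80),
    (17.39, 16.81),
    (18.15, 12.36),
    (30.41, 17.15),
    (35.78, 18.08),
    (36.42, 18.21),
    (27.21, 16.97),
]

WORKED_EXAMPLE_UNITS = [
    (5, 4), (4, 4), (4, 4), (4, 3), (7, 4), (8, 4), (8, 4), (6, 4),
]

WORKED_EXAMPLE_Q = 423


@pytest.fixture(scope="session")
def phantom_suite():
    """50 seeded phantoms for direction-robustness style checks."""
    return sample_cohort_phantoms(50, seed=21)


@pytest.fixture(scope="session")
def predictor_pool():
    """Measured phantom library shared by cohort-simulation tests."""
    return phantom_predictor_pool(240, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
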