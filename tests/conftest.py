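import numpy as np
import pytest

from tesgroup.cohort import CohortSpec, generate_cohort
from tesgroup.geometry import icosphere


@pytest.fixture(scope="session")
def cohort6():
    """Default-condition 6-subject cohort (features off: not needed here)."""
    return generate_cohort(CohortSpec(n_subjects=6, seed=101, compute_features=False))


@pytest.fixture(scope="session")
def subject(cohort6):
    return cohort6[0]


@pytest.fixture(scope="session")
def featured_cohort():
    """Small cohort with anatomical features at reduced mesh resolution."""
    return generate_cohort(
        CohortSpec(n_subjects=5, seed=7, surface_subdivisions=2, tet_subdivisions=2)
    )


@pytest.fixture(scope="session")
def sphere642():
    return icosphere(3, 80.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
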