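import numpy as np
import pytest

from looptrax.cohort_io import default_schema
from looptrax.simulate import CohortModel, simulate_cohort
from looptrax.trajectory import with_trajectory_groups


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def cohort(schema):
    """Default-sized synthetic cohort (n=43, sparse missingness)."""
    return with_trajectory_groups(simulate_cohort(CohortModel(seed=2), schema))


@pytest.fixture(scope="session")
def clean_cohort(schema):
    """Synthetic cohort with no missing values."""
    return with_trajectory_groups(
        simulate_cohort(CohortModel(n=60, missing_rates={}, seed=5), schema)
    )
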