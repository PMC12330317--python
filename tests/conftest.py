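import numpy as np
import pytest
from hypothesis import settings

from vpcue.observer import CohortConfig, simulate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def expt1_cohort():
    """A small fixed-seed two-session cohort with SAI traces."""
    return simulate_cohort(CohortConfig(experiment="expt1", n_per_group=8, seed=42))


@pytest.fixture(scope="session")
def expt2_cohort():
    """A small fixed-seed three-group cTBS cohort."""
    return simulate_cohort(CohortConfig(experiment="expt2", n_per_group=6, seed=43))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
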