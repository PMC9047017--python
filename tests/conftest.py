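import warnings

import numpy as np
import pytest

from hubfail import CohortConfig, generate_cohort

# near-constant post-attack sums legitimately trigger scipy's precision
# warning in a handful of replicate t-tests; it is not a defect signal
warnings.filterwarnings(
    "ignore", message="Precision loss occurred", category=RuntimeWarning
)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A cohort small enough for fast unit tests but structurally complete."""
    return CohortConfig(
        n_regions=30,
        rich_set_size=3,
        n_subjects_per_group=8,
        n_timepoints=80,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_cohort(small_config, validate_network=False)


@pytest.fixture(scope="session")
def default_panel():
    """One default-size cohort, shared across tests that need realism."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
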