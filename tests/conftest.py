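import numpy as np
import pytest

from gcaconn.synth import CohortConfig, generate_cohort, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Desk-miniature cohort: 4 sites, 20 parcels in 5 networks."""
    return CohortConfig(
        n_sites=4, subjects_per_site=(50, 60), n_parcels=20, n_networks=5, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
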