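import numpy as np
import pytest

import areamix as am

# three mixture centers in 4-D with pairwise 5-SD separation (unit spherical
# covariance) — the canonical "clearly clustered" fixture
SEPARATED_MEANS = np.array([
    [0.0, 0.0, 0.0, 0.0],
    [5.0, 0.0, 5.0, 0.0],
    [0.0, 5.0, 0.0, 5.0],
])


def separated_mixture_config(seed, n_units=300, n_noise_vars=0):
    """3 well-separated spherical components; every coordinate informative."""
    return am.SimulationConfig(
        n_units=n_units, k_true=3, weights=np.ones(3) / 3,
        cluster_means=SEPARATED_MEANS, covariance_spec=("spherical", 1.0),
        n_noise_vars=n_noise_vars, seed=seed)


@pytest.fixture(scope="session")
def county_dataset():
    """One default-scale synthetic county dataset shared across tests."""
    return am.generate_county_table(am.SimulationConfig(seed=20))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
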