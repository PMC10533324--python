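import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from belugapreg.mixture import MCMCSettings, fit_mixture
from belugapreg.synthetic import KNOWN_STATUS_GROUPS, simulate_known_samples

settings.register_profile(
    "derandomized",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def fast_settings() -> MCMCSettings:
    """Short chain geometry for unit tests (1000 retained draws x 2 chains)."""
    return MCMCSettings(n_iterations=3000, n_chains=2, thin=2, burn_in=1000, seed=17)


@pytest.fixture(scope="session")
def carcass_table():
    """Synthetic known-status carcass-like table (seven status groups)."""
    return simulate_known_samples(KNOWN_STATUS_GROUPS, seed=1)


@pytest.fixture(scope="session")
def carcass_logbp(carcass_table):
    return np.log(carcass_table["bp_tissue_ng_g"].to_numpy(dtype=float))


@pytest.fixture(scope="session")
def carcass_fit2(carcass_logbp, fast_settings):
    """Two-component mixture fit shared across tests."""
    return fit_mixture(carcass_logbp, 2, fast_settings)
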