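import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import symflux as sf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_noiseless():
    """A 2 species x 2 CO2 x 3 pot campaign with all noise off."""
    design, truth = sf.scenario_liverwort_co2(noise=False, replicates_per_cell=3)
    campaign, truth_record = sf.simulate_campaign(design, truth, seed=11)
    return design, truth, campaign, truth_record


@pytest.fixture(scope="session")
def small_noisy():
    """Same layout with Poisson counting noise, IRMS noise and pot-level CV."""
    design, truth = sf.scenario_liverwort_co2(noise=True, replicates_per_cell=4)
    campaign, truth_record = sf.simulate_campaign(design, truth, seed=7)
    return design, truth, campaign, truth_record


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
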