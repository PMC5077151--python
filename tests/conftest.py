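import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from spliceratio.synthetic import SimCohortConfig, make_event_panel, simulate_cohort


@pytest.fixture(scope="session")
def small_panel():
    """300-event panel with mutant-responsive affinities and a toy genome."""
    return make_event_panel(n_events=300, seed=7, responsive_fraction=0.2)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    """Default-condition cohort on the small panel (30 WT + 13 mutant)."""
    config = SimCohortConfig(noise_seed=8)
    return simulate_cohort(small_panel.sim_events, config), config


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
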