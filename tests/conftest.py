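import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isobolo import PDParams, RunConfig, build_ladder, default_arms, simulate_study
from isobolo.metrics import cohort_metrics

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ladder():
    return build_ladder()


@pytest.fixture(scope="session")
def synergy_params():
    """Ground truth of the emulated study: true ED50s and gamma = 0.524."""
    return PDParams(gamma_true=0.524)


@pytest.fixture(scope="session")
def synergy_config(synergy_params):
    return RunConfig(seed=1, params=synergy_params)


@pytest.fixture(scope="session")
def synergy_cohort(synergy_params):
    arms = default_arms(synergy_params)
    return simulate_study(arms, synergy_params, seed=1)


@pytest.fixture(scope="session")
def synergy_metrics(synergy_cohort):
    return cohort_metrics(synergy_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1)
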