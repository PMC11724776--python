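import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from med4child import ffq as ffq_mod  # noqa: E402
from med4child import scoring as scoring_mod  # noqa: E402
from med4child import simulate as simulate_mod  # noqa: E402


@pytest.fixture(scope="session")
def registry():
    return scoring_mod.load_registry()


@pytest.fixture(scope="session")
def registry_index(registry):
    return scoring_mod.registry_index(registry)


@pytest.fixture(scope="session")
def mapping():
    return ffq_mod.load_mapping()


@pytest.fixture(scope="session")
def small_calibrated_cohort():
    """Calibrated cohort with no misreporting, small n for fast tests."""
    return simulate_mod.generate_cohort(simulate_mod.preset_calibrated(n=400, seed=11))


@pytest.fixture(scope="session")
def biased_cohort():
    """Cohort with social-desirability misreporting."""
    return simulate_mod.generate_cohort(simulate_mod.preset_biased(n=2000, seed=5))
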