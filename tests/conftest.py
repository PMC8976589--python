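import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from neolos.synthetic_cohort import default_config_from_table1, generate  # noqa: E402


@pytest.fixture(scope="session")
def default_synthetic():
    """One default-calibration synthetic cohort, fixed seed."""
    return generate(default_config_from_table1(seed=7))


@pytest.fixture(scope="session")
def default_cohort(default_synthetic):
    return default_synthetic.cohort
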