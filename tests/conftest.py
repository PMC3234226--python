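import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "cidrive",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("cidrive")


@pytest.fixture(scope="session")
def fixture_dataset():
    from cidrive import table1_fixture

    return table1_fixture()


@pytest.fixture(scope="session")
def fixture_chain(fixture_dataset):
    """One default-length posterior chain on the packaged dataset, shared
    across tests that only read it."""
    from cidrive import MCMCConfig, run_mcmc

    return run_mcmc(fixture_dataset, MCMCConfig(seed=1))
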