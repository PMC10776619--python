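import pytest

from brcascreen import builtin_scenario, default_config, run_scenario


@pytest.fixture(scope="session")
def central():
    return builtin_scenario("central")


@pytest.fixture(scope="session")
def best():
    return builtin_scenario("best")


@pytest.fixture(scope="session")
def worst():
    return builtin_scenario("worst")


@pytest.fixture(scope="session")
def central_runs(central):
    """All three models, three generations, central scenario."""
    return run_scenario(central)


@pytest.fixture(scope="session")
def configs():
    return {m: default_config(m) for m in (1, 2, 3)}
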