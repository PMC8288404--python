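import pytest

from carbonledger import McConfig, SynthConfig, generate_budget_table, run_monte_carlo


@pytest.fixture(scope="session")
def default_table():
    """The default synthetic nine-region budget table."""
    return generate_budget_table(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def mc_result(default_table):
    """A full-size Monte-Carlo run shared across tests."""
    return run_monte_carlo(default_table, McConfig(n_draws=100_000, seed=123))
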