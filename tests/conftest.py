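import pytest

from polytill import popsim


@pytest.fixture(scope="session")
def fx():
    """The deterministic benchmark gene pairs + mutation table."""
    return popsim.benchmark_fixtures()


@pytest.fixture(scope="session")
def table_population(fx):
    """The screened population carrying exactly the confirmed-mutation table."""
    return popsim.population_from_table(fx)
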