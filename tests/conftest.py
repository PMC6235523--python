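import hypothesis
import numpy as np
import pytest

from ncskit import synthetic
from ncskit.report import portfolio_from_params

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_table():
    """The 21-pathway published-headline parameter table."""
    return synthetic.generate_parameter_table()


@pytest.fixture(scope="session")
def fixture_portfolio(fixture_table):
    return portfolio_from_params(fixture_table)


@pytest.fixture(scope="session")
def toy_landscape():
    return synthetic.generate_landscape(
        synthetic.SyntheticConfig(seed=7, shape=(30, 40))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
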