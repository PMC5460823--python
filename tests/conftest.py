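import numpy as np
import pytest

from bivpois.synthetic import generate, scenario_suite


@pytest.fixture(scope="session")
def suite():
    return scenario_suite()


@pytest.fixture(scope="session")
def well_specified_data(suite):
    """One moderate well-specified dataset shared across read-only tests."""
    data, truth = generate(suite["well_specified"], n=3000, seed=42)
    return data, truth


@pytest.fixture(scope="session")
def truncated_data(suite):
    data, truth = generate(suite["truncated_tight"], n=3000, seed=43)
    return data, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
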