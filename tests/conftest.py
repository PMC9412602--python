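import numpy as np
import pytest

from ironmr.datasets import table1_bma_input, table1_fixture, table1_records


@pytest.fixture(scope="session")
def fixture_sets():
    """Harmonised instrument sets per biomarker from the packaged table."""
    return table1_fixture()


@pytest.fixture(scope="session")
def fixture_records():
    return table1_records()


@pytest.fixture(scope="session")
def bma_input():
    return table1_bma_input()


@pytest.fixture
def rng():
    return np.random.default_rng(20220809)
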