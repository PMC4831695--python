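import numpy as np
import pytest

from uparsim.cli_io import make_fixture
from uparsim.parameters import baseline_parameter_set


@pytest.fixture(scope="session")
def params():
    return baseline_parameter_set()


@pytest.fixture()
def paper_initial():
    return make_fixture("paper-initial", 32, seed=0)


@pytest.fixture()
def bump_fixture():
    return make_fixture("bump", 48, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
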