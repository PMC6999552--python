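import numpy as np
import pytest

from iblgames import AgentParams, make_condition


@pytest.fixture
def eqp():
    return make_condition("EQP")


@pytest.fixture
def pdf():
    return make_condition("PDF")


@pytest.fixture
def pdm():
    return make_condition("PDM")


@pytest.fixture
def actr_params():
    return AgentParams(d=0.5, sigma=0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
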