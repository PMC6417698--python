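import numpy as np
import pytest

from ecorisk.synthetic import gen_concentrations, gen_toxicity, laizhou_scenario


@pytest.fixture(scope="session")
def scenarios():
    return laizhou_scenario()


@pytest.fixture(scope="session")
def conc_records(scenarios):
    conc_sc, _ = scenarios
    return gen_concentrations(conc_sc, seed=11)


@pytest.fixture(scope="session")
def tox_records(scenarios):
    _, tox_sc = scenarios
    return gen_toxicity(tox_sc, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
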