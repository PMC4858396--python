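import numpy as np
import pytest

from toxprofiler import synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimulationConfig(n_compounds=200, seed=11)


@pytest.fixture(scope="session")
def small_library(small_config):
    return synthetic.generate_library(small_config)


@pytest.fixture(scope="session")
def large_library():
    cfg = synthetic.SimulationConfig(n_compounds=2000, seed=7)
    return synthetic.generate_library(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
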