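import numpy as np
import pytest

from bromonet import SimulationConfig, load_compound_library


@pytest.fixture(scope="session")
def library():
    return load_compound_library()


@pytest.fixture(scope="session")
def model(library):
    """Lookup a depsipeptide model by compound name."""

    def get(name):
        comp = next(c for c in library if c.name == name)
        assert comp.model is not None
        return comp.model

    return get


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=42)
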