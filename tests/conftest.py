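import numpy as np
import pytest

from invbreak.config import ConfigDefaults
from invbreak.simulate import _random_seq


@pytest.fixture(scope="session")
def cfg():
    return ConfigDefaults()


@pytest.fixture(scope="session")
def te_library():
    rng = np.random.default_rng(424242)
    return {"BuT5": _random_seq(rng, 981), "Galileo": _random_seq(rng, 1200)}


@pytest.fixture(scope="session")
def comparative_map():
    """One noiseless simulated comparative map shared across tests."""
    from invbreak.simulate import simulate_comparative_map

    return simulate_comparative_map(11)
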