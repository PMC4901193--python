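import warnings

import numpy as np
import pytest
from hypothesis import settings

from tvcoupling.evaluation import fixture_6node_analogue, simulate_from_config

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def six_node_run():
    """One shared noiseless 6-node simulation (system + ensemble)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        system, ensemble = simulate_from_config(fixture_6node_analogue(0))
    return system, ensemble


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
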