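import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from clonalsnv.simulate import SimulationConfig, simulate_genealogy


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=11)


@pytest.fixture
def genealogy(sim_config):
    return simulate_genealogy(4, sim_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
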