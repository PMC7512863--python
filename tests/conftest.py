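import sys
from pathlib import Path

import numpy as np
import pytest

import sympair as sp

sys.path.insert(0, str(Path(__file__).parent))

from helpers import ScriptedRng  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scripted_rng():
    return ScriptedRng


@pytest.fixture
def tiny_config():
    """A very small, fast simulation configuration."""
    return sp.SimulationConfig(
        landscape="rastrigin",
        initial_population=40,
        total_resource=200.0,
        steps=50,
        snapshot_every=25,
        seed=7,
    )
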