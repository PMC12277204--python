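import numpy as np
import pytest

from rtmsim.engines import EngineConfig, Mode, SessionTrace


@pytest.fixture
def open_cfg():
    return EngineConfig(mode=Mode.OPEN_LOOP, open_interval_min=10.0)


@pytest.fixture
def closed_lower_cfg():
    return EngineConfig(mode=Mode.CLOSED_LOOP, countdown_min=2.0)


@pytest.fixture
def closed_higher_cfg():
    return EngineConfig(mode=Mode.CLOSED_LOOP, countdown_min=5.0)


@pytest.fixture
def immobile_3hr_trace():
    """A full 3-hr wearing session with no arm movement, instant button."""
    return SessionTrace(movement_flags=(False,) * 5400, ack_policy=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
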