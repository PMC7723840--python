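import numpy as np
import pytest

from pvcouple.core import LfpTrace, StateInterval
from pvcouple.synthetic import SyntheticConfig, generate_session


@pytest.fixture(scope="session")
def default_bundle():
    """One 120 s synthetic session shared by read-only tests."""
    return generate_session(SyntheticConfig(seed=11, total_duration=120.0))


@pytest.fixture()
def tone_trace():
    """10 s unit-amplitude 6 Hz sine at 1 kHz."""
    t = np.arange(0, 10.0, 0.001)
    return LfpTrace(np.sin(2 * np.pi * 6.0 * t), 1000.0)


@pytest.fixture()
def sws_states():
    return [StateInterval("SWS", 0.0, 200.0)]
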