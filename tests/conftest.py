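import numpy as np
import pytest

from neuralinertia import (
    ConcentrationProtocol,
    ProtocolStep,
    default_protocol,
)


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture
def toy_protocol():
    """Short titration used for hand-checkable endpoint examples:
    ascending 0.25/0.50/0.75/1.00, descending 0.60/0.40/0.20, 10-min dwells."""
    steps = [ProtocolStep(c, 10.0, "ascending") for c in (0.25, 0.5, 0.75, 1.0)]
    steps += [ProtocolStep(c, 10.0, "descending") for c in (0.6, 0.4, 0.2)]
    return ConcentrationProtocol(tuple(steps), pre_window_minutes=15.0,
                                 post_window_minutes=120.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
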