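import numpy as np
import pytest

from smikit.protocol import default_protocol


@pytest.fixture(scope="session")
def proto():
    """Canonical two-shell clinical protocol (4 b0, 20 b=1, 60 b=2)."""
    return default_protocol(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
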