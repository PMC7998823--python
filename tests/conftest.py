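import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rri_like(rng):
    """A plausible 320-beat RR-interval series in ms."""
    return 940 + 40 * np.sin(2 * np.pi * np.arange(320) / 25) + rng.normal(0, 15, 320)
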