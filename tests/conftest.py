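import numpy as np
import pytest

from hdmea.chip import ChipGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geometry():
    """4x4 sub-grid at full sampling rate; keeps raw-trace tests fast."""
    return ChipGeometry(n_rows=4, n_cols=4)


@pytest.fixture
def default_geometry():
    return ChipGeometry()
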