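import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_chain():
    """A straight 165 nm polyline with 2.5 nm vertex spacing."""
    import afmscan as a
    pts = np.column_stack([np.linspace(0.0, 165.0, 67), np.zeros(67)])
    return a.PolylineTrace(0, pts)
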