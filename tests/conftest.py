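import numpy as np
import pytest

import circalab as cl


@pytest.fixture
def quiet_wt():
    """Jitter-free wild-type-like parameters: onsets land exactly on
    lights-off, convenient for exact assertions."""
    return cl.make_params("wt_like", seed=0, onset_jitter_min=0.0)


@pytest.fixture
def ld10():
    return cl.Protocol([cl.LD(10)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
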