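import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def rand_sym(rng, p, scale=1.0):
    """Random symmetric matrix helper shared across test modules."""
    a = rng.standard_normal((p, p)) * scale
    return 0.5 * (a + a.T)
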