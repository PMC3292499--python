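import numpy as np
import pytest

from tdthet import EMSettings, TrioCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20120113)


@pytest.fixture
def fast_settings():
    """Small but adequate EM settings for unit tests."""
    return EMSettings(n_starts=50, seed=1)


@pytest.fixture
def random_counts():
    """Factory for random 10-cell count vectors."""

    def make(n=200, seed=0, concentration=1.0):
        r = np.random.default_rng(seed)
        probs = r.dirichlet(np.full(10, concentration))
        return TrioCounts(r.multinomial(n, probs))

    return make
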