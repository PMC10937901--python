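import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(p, rng, cond=10.0):
    """A random well-conditioned SPD matrix (for oracle tests)."""
    Q, _ = np.linalg.qr(rng.standard_normal((p, p)))
    eigs = np.linspace(1.0, cond, p)
    return (Q * eigs) @ Q.T


@pytest.fixture
def spd5(rng):
    return random_spd(5, rng)
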