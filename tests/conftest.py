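import numpy as np
import pytest

import siamreg as sr


@pytest.fixture(scope="session")
def tiny_phantom():
    """A small undeformed two-modality phantom shared across tests."""
    return sr.make_phantom(sr.PhantomConfig(extents=(32, 32, 32), seed=7))


@pytest.fixture(scope="session")
def tiny_pair(tiny_phantom):
    """A deformed pair with ground-truth field at moderate amplitude."""
    return sr.make_deformed_pair(
        tiny_phantom, sr.DeformConfig(amplitude=2.5, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def numeric_gradient(f, x, eps=1e-5):
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f(x)
        x[i] -= 2 * eps
        fm = f(x)
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
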