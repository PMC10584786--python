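import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_volume():
    """One deterministic metastasis-like volume reused across tests."""
    from qradbrain.synthetic import gen_volume

    return gen_volume(label=-1, seed=7)


def random_unit_amplitudes(rng, n=1):
    a = np.abs(rng.standard_normal((n, 4)))
    return a / np.linalg.norm(a, axis=1, keepdims=True)
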