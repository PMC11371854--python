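import numpy as np
import pytest

from liquidecg import ModelConfig, SynthConfig, build_model, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """28 synthetic records (4 per group), shared across tests."""
    records, manifest = generate_dataset(SynthConfig(n_records=28, seed=5))
    return records, manifest


@pytest.fixture(scope="session")
def default_model():
    return build_model(ModelConfig(), seed=0)


def finite_difference(fn, x, eps=1e-6):
    """Central finite-difference gradient of scalar fn at ndarray x."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (fn(xp) - fn(xm)) / (2 * eps)
    return g
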