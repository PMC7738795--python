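import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_proba():
    """Factory for random probability matrices with Dirichlet rows."""

    def make(n, c, seed=0, concentration=1.0):
        r = np.random.default_rng(seed)
        return r.dirichlet(np.full(c, concentration), size=n)

    return make


@pytest.fixture
def imbalanced_instance():
    """A 90/10 two-class instance where the minority is systematically
    less confident than every majority sample: a single global cutoff at
    matched budget picks majority only, per-class thresholds do not."""
    maj = np.array([[0.90 + i * 0.001, 0.10 - i * 0.001] for i in range(90)])
    mino = np.array([[0.45 - i * 0.005, 0.55 + i * 0.005] for i in range(10)])
    return np.vstack([maj, mino])
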