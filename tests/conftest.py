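import numpy as np
import pytest

from direct_rna import rbm, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model(rng):
    """Random enumerable RBM (5 visible, 3 hidden)."""
    return rbm.RBMModel(
        weight=rng.normal(0, 0.5, (5, 3)),
        visible_bias=rng.normal(0, 0.5, 5),
        hidden_bias=rng.normal(0, 0.5, 3),
    )


@pytest.fixture(scope="session")
def small_instance():
    """One small synthetic study case shared across tests."""
    return synthetic.make_instance(length=60, n_members=10, n_planted=8, seed=42)
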