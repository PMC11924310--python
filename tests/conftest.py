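import numpy as np
import pytest

from polartrait import synthetic, thermal


@pytest.fixture
def arctic_gradient():
    """The arctic thermal gradient used throughout the synthetic experiments."""
    return [-0.5, 2.3, 5.0, 7.3, 9.9, 12.3, 15.0]


@pytest.fixture
def tpc_truth():
    """Arctic-like thermal performance curve: t_opt ~ 10.9, mu_max ~ 0.7."""
    return thermal.TPCParams(a=0.45, b=0.05, z=7.0, w=26.0)


@pytest.fixture
def caas_dataset():
    """One deterministic planted-CAAS dataset (3 clusters)."""
    return synthetic.simulate_caas_dataset(n_clusters=3, length=200, n_planted=3, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
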