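import numpy as np
import pytest

from osteosae.synthetic import FeatureGenSpec, generate_features


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_blobs():
    """Well-separated 3-class Gaussian features (the separable-data oracle)."""
    X, y = generate_features(FeatureGenSpec(n_per_class=(50, 50, 50), dim=10, separation=6.0, seed=11))
    return X, y


@pytest.fixture(scope="session")
def tiny_sae_fixture(rng):
    """A small random SAE + batch for gradient and loss checks."""
    from osteosae.dssae import SparseAutoencoder

    sae = SparseAutoencoder.init(6, 4, np.random.default_rng(3), rho=0.05, c_s=1.0, c_w=1e-4)
    Y = np.random.default_rng(4).uniform(0.1, 0.9, size=(5, 6))
    return sae, Y
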