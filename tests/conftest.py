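import numpy as np
import pytest

from stochact import SynthClassSpec, gen_classification, tiny_cnn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240314)


@pytest.fixture(scope="session")
def small_cnn():
    """3-slot classifier on 16x16 inputs, small enough for exhaustive checks."""
    return tiny_cnn(3, n_act_layers=3, seed=11, image_size=(16, 16, 3), width=4)


@pytest.fixture(scope="session")
def texture_2class():
    """Noise-free, perfectly separable 2-class texture set."""
    spec = SynthClassSpec(n_classes=2, n_per_class=30, noise_sd=0.0, seed=7)
    images, labels = gen_classification(spec)
    return spec, images, labels
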