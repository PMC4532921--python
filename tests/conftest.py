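import numpy as np
import pytest

from divrbm import rbm, stimuli


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_rbm(nv, nh, seed=0, scale=0.5):
    """A small random RBM with nonzero biases, for oracle tests."""
    r = np.random.default_rng(seed)
    return rbm.RBMParams(
        W=scale * r.standard_normal((nv, nh)),
        b=scale * r.standard_normal(nh),
        c=scale * r.standard_normal(nv),
    )


def random_binary_data(nv, n_rows, seed=0):
    r = np.random.default_rng(seed)
    return (r.random((n_rows, nv)) < 0.5).astype(float)


@pytest.fixture(scope="session")
def tiny_patchset():
    """A small preprocessed patch set (5x5 patches) for fast pipeline tests."""
    images = stimuli.generate_synthetic_images(3, 64, seed=7)
    return stimuli.prepare_patches(
        images, n_patches=300, patch_side=5, seed=7, variance_threshold=0.05
    )
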