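import numpy as np
import pytest
from scipy import ndimage

from gwcine import CineSequence, DeformationSequence, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_image(rng):
    """Smooth non-degenerate 2D texture in [0, 1]."""
    img = ndimage.gaussian_filter(rng.random((32, 32)), 1.0)
    return (img - img.min()) / (img.max() - img.min())


@pytest.fixture
def small_sequence(rng):
    """6-frame 32x32 sequence of smooth random textures."""
    frames = np.stack(
        [ndimage.gaussian_filter(rng.random((32, 32)), 1.5) for _ in range(6)]
    )
    return CineSequence(frames)


@pytest.fixture(scope="session")
def default_phantom():
    spec = PhantomSpec(seed=7)
    seq, gt = generate_phantom(spec)
    return spec, seq, gt


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(noise_std=0.0, seed=11)
    seq, gt = generate_phantom(spec)
    return spec, seq, gt
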