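import numpy as np
import pytest
from scipy import ndimage

from chronoatlas.grids import ImageVolume
from chronoatlas.phantoms import make_phantom
from chronoatlas.transforms import DisplacementField, scaling_and_squaring


@pytest.fixture(scope="session")
def phantom64():
    """Small base phantom shared by read-only tests."""
    return make_phantom(size=64, seed=0)


@pytest.fixture(scope="session")
def phantom96():
    return make_phantom(size=96, seed=0)


def random_smooth_field(shape, amplitude, sigma, rng, spacing=1.0):
    """Random Gaussian-smoothed displacement field (mm), max norm = amplitude voxels."""
    rank = len(shape)
    v = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(rank)],
        axis=-1,
    )
    norms = np.linalg.norm(v, axis=-1)
    if norms.max() > 0:
        v *= amplitude / norms.max()
    return DisplacementField(v * spacing, (spacing,) * rank)


def random_diffeo_pair(shape, amplitude, sigma, rng, spacing=1.0):
    """(forward, inverse) diffeomorphic displacement fields from one SVF."""
    vel = random_smooth_field(shape, amplitude, sigma, rng, spacing)
    fwd = scaling_and_squaring(vel)
    inv = scaling_and_squaring(DisplacementField(-vel.vectors, vel.spacing, vel.origin))
    return fwd, inv


def smooth_image(shape, rng, sigma=3.0):
    """Random smooth test image with order-one intensity variation."""
    img = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    rngv = img.max() - img.min()
    return ImageVolume((img - img.min()) / (rngv if rngv else 1.0))
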