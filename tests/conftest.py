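"""Shared fixtures: small grids, masks and synthetic volumes."""

import numpy as np
import pytest

from vbasym.asymmetry import HemisphereMask
from vbasym.io_core import GreyMatterVolume, make_affine


@pytest.fixture
def small_affine():
    return make_affine((17, 16, 16), 3.0)


@pytest.fixture
def small_volume(small_affine):
    rng = np.random.default_rng(42)
    data = rng.random((17, 16, 16))
    return GreyMatterVolume(data, small_affine)


@pytest.fixture
def gaussian_blob():
    """Centered Gaussian blob on a 49x48x48 grid at 3 mm (odd x, midline column)."""
    shape = (49, 48, 48)
    aff = make_affine(shape, 3.0)
    idx = np.indices(shape, dtype=float)
    c = np.array([24.0, 24.0, 24.0])
    r2 = sum((idx[i] - c[i]) ** 2 for i in range(3))
    data = np.exp(-r2 / (2 * 5.0**2))
    return GreyMatterVolume(data, aff)


@pytest.fixture
def right_mask(small_affine):
    mask = np.zeros((17, 16, 16), dtype=bool)
    mask[9:, :, :] = True  # world x > 0 voxels for the 17-column centred grid
    return HemisphereMask(mask, small_affine)
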