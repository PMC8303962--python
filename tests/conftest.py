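"""Shared fixtures: small deterministic volumes and phantoms."""

import numpy as np
import pytest

from orthoreg import Volume, make_phantom, threshold_bone


@pytest.fixture(scope="session")
def phantom_pair():
    """Standard 64^3 head phantom and its landmarks (seeded)."""
    return make_phantom(seed=7)


@pytest.fixture(scope="session")
def bone_volume(phantom_pair):
    vol, _ = phantom_pair
    return threshold_bone(vol)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def smooth_volume():
    """Smooth separable intensity field on a 16^3 grid, anisotropic spacing."""
    n = 16
    x = np.linspace(0, 1, n)
    xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
    vox = np.sin(2 * np.pi * xx) * np.cos(np.pi * yy) + zz
    return Volume(vox, spacing=(1.0, 1.5, 2.0), origin=(-3.0, 1.0, 2.0))


@pytest.fixture()
def random_volume(rng):
    return Volume(rng.normal(size=(8, 8, 8)), spacing=(1.0, 1.0, 1.0),
                  origin=(0.0, 0.0, 0.0))
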