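import numpy as np
import pytest

from fetadc import PhantomSpec, ScalarVolume, VoxelMask, generate_phantom

SPACING = (2.32, 2.32, 2.03)


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Default 48-cube phantom, no noise, TBR 2.0."""
    return generate_phantom(PhantomSpec(grid_shape=(48, 48, 48), seed=7))


@pytest.fixture(scope="session")
def noise_free_bundle_64():
    """64-cube phantom matching the full-size validation geometry."""
    return generate_phantom(PhantomSpec(grid_shape=(64, 64, 64), seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_volume(values, spacing=SPACING, modality="FET_SUV", units=""):
    return ScalarVolume(np.asarray(values, dtype=float), spacing, modality, units)


def make_mask(flags, spacing=SPACING):
    return VoxelMask(np.asarray(flags, dtype=bool), spacing)
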