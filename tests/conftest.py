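import numpy as np
import pytest

from voldvc import Mask, generate_speckle

VOXEL_SIZE = 0.5  # mm, clinical-MRI-like isotropic resolution


@pytest.fixture(scope="session")
def small_speckle():
    """Default-texture speckle model + volume on a 64^3 grid."""
    model, vol = generate_speckle((64, 64, 64), VOXEL_SIZE, seed=11)
    return model, vol


@pytest.fixture(scope="session")
def fine_speckle():
    """Finer speckle (1.2-voxel blobs, denser) for shift-recovery tests.

    The single-pass FFT approach needs several independent speckles per
    window to dominate its circular-wraparound contamination; blobs at
    ~1 voxel scale provide that without changing any engine default.
    """
    model, vol = generate_speckle(
        (64, 64, 64), VOXEL_SIZE, blob_density=0.02, blob_sigma=0.6, seed=12
    )
    return model, vol


@pytest.fixture(scope="session")
def full_mask_64():
    return Mask(np.ones((64, 64, 64), dtype=np.uint8))
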