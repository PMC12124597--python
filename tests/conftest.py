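import numpy as np
import pytest

from risp import (
    AcquisitionParams,
    ImageGrid,
    make_disk_phantom,
    make_ring_array,
    simulate_channel_data,
)


@pytest.fixture(scope="session")
def small_grid():
    """64x64 grid at 0.4 mm spacing, centered on the origin."""
    return ImageGrid((64, 64), (4.0e-4, 4.0e-4))


@pytest.fixture(scope="session")
def ring32():
    """32-element ring of radius 2 cm around the origin."""
    return make_ring_array(32, 0.02)


@pytest.fixture(scope="session")
def acq():
    """Sampling that resolves one 0.2 mm shell per sample out to ~5 cm."""
    return AcquisitionParams(sound_speed=1500.0, sampling_rate=7.5e6, n_samples=256)


@pytest.fixture(scope="session")
def offcenter_disk(small_grid):
    return make_disk_phantom(
        small_grid, [((-0.004, -0.003), 0.0025, 1.0), ((0.005, 0.004), 0.0015, 0.8)]
    )


@pytest.fixture(scope="session")
def ring_data(offcenter_disk, ring32, acq):
    """Simulated channel data for the off-center disk phantom."""
    return simulate_channel_data(offcenter_disk, ring32, acq)


@pytest.fixture(scope="session")
def odd_grid():
    """65x65 grid: its central voxel center sits exactly at the origin."""
    return ImageGrid((65, 65), (4.0e-4, 4.0e-4))


@pytest.fixture(scope="session")
def centered_point_data(odd_grid, ring32, acq):
    """A single super-voxel source at the exact grid center."""
    phantom = make_disk_phantom(odd_grid, [((0.0, 0.0), 1.0e-4, 1.0)])
    return simulate_channel_data(phantom, ring32, acq), phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
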