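import numpy as np
import pytest

from slicekin.calibration import VolumeMapping
from slicekin.imaging import T1_LIKE, SliceSpec
from slicekin.phantom import GridSpec, default_scene_solids, generate_grid_scan


@pytest.fixture(scope="session")
def grid_spec():
    return GridSpec()


@pytest.fixture(scope="session")
def noiseless_scans(grid_spec):
    return generate_grid_scan(grid_spec, seed=11, noise_sigma=0.0, blur_fwhm=1.0)


@pytest.fixture(scope="session")
def noisy_scans(grid_spec):
    return generate_grid_scan(grid_spec, seed=11, noise_sigma=0.05, blur_fwhm=1.0)


@pytest.fixture(scope="session")
def solids():
    return default_scene_solids()


@pytest.fixture()
def identity_mapping():
    return VolumeMapping.identity()


@pytest.fixture(scope="session")
def sagittal_t1_clean():
    """Noiseless, unblurred T1-like mid-sagittal slice through the cubes."""
    return SliceSpec(**T1_LIKE, origin=np.array([0.0, 0.0, 35.0]),
                     normal=np.array([1.0, 0.0, 0.0]),
                     u_axis=np.array([0.0, 0.0, 1.0]))
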