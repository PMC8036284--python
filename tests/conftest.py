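import numpy as np
import pytest

from pculfdg import FocusSpec, PhantomSpec, generate_phantom
from pculfdg.contours import SliceImage


def gaussian_image(shape=(60, 60), center=(30.0, 30.0), sigma=5.0, peak=1.0, background=0.0):
    """A single-focus normalised-scale test slice (1 mm pixels)."""
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    v = background + peak * np.exp(
        -((r - center[0]) ** 2 + (c - center[1]) ** 2) / (2 * sigma**2)
    )
    return SliceImage(values=v, spacing_mm=1.0)


@pytest.fixture(scope="session")
def static_phantom_spec():
    """Single stable focus at a voxel-aligned centre, no noise."""
    return PhantomSpec(
        grid_shape=(10, 33, 33),
        in_plane_spacing_mm=3.0,
        nodule_center_mm=(14.85, 48.0, 48.0),  # slice 4.5, voxel (16, 16)
        nodule_radius_mm=12.0,
        foci=(FocusSpec(amplitude=5.0, sigma_mm=5.0),),
        noise_sd=0.0,
        target_suvmax=6.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def static_phantom(static_phantom_spec):
    return generate_phantom(static_phantom_spec)


@pytest.fixture(scope="session")
def drift_phantom_spec():
    """One focus drifting 2 mm per slice in-plane, no noise, 1 mm pixels."""
    return PhantomSpec(
        grid_shape=(9, 61, 61),
        in_plane_spacing_mm=1.0,
        slice_thickness_mm=3.3,
        nodule_center_mm=(13.2, 30.0, 30.0),  # central slice 4
        nodule_radius_mm=14.0,
        foci=(FocusSpec(amplitude=5.0, sigma_mm=4.0, drift_mm_per_slice=(0.0, 2.0)),),
        noise_sd=0.0,
        target_suvmax=8.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def drift_phantom(drift_phantom_spec):
    return generate_phantom(drift_phantom_spec)
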