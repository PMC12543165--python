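import logging

import numpy as np
import pytest

from vesselleak import phantom

logging.getLogger("vesselleak").setLevel(logging.ERROR)


def voxelize_cylinder(radius_um, voxel_size_um=(2.0, 0.692, 0.692),
                      shape=(20, 61, 61), axis_center=None):
    """Independent oracle: vertical cylinder mask from the analytic
    inequality, no package code involved."""
    vz, vy, vx = voxel_size_um
    zz, yy, xx = np.indices(shape)
    if axis_center is None:
        axis_center = ((shape[1] - 1) / 2, (shape[2] - 1) / 2)
    cy, cx = axis_center
    d2 = ((yy - cy) * vy) ** 2 + ((xx - cx) * vx) ** 2
    return d2 <= radius_um**2


@pytest.fixture(scope="session")
def small_spec():
    return phantom.PhantomSpec(
        volume_shape=(16, 72, 72), frame_interval_s=90.0, seed=11,
        capillary_density=25.0,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    _, truth = phantom.make_vascular_phantom(small_spec)
    return truth


@pytest.fixture(scope="session")
def noiseless_kinetics():
    return phantom.KineticsSpec(noise_sigma=0.0, psf_fwhm_um=0.0,
                                vignette_strength=0.0, background=0.0,
                                ktrans_jitter_sd=0.0)
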