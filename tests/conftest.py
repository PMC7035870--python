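import numpy as np
import pytest

import boldsim as bs


@pytest.fixture(scope="session")
def desk_template():
    """Default ellipsoid template at the desk-scale grid."""
    return bs.synthetic_template(dims=(24, 24, 16), voxel_size=(3.0, 3.0, 3.5), seed=0)


@pytest.fixture(scope="session")
def desk_mask(desk_template):
    return bs.compute_mask(desk_template)


@pytest.fixture(scope="session")
def fitted_scan(desk_template, desk_mask):
    """One fitted simulation at default noise parameters, reused read-only."""
    params = bs.NoiseParameters(snr=30.0, sfnr=70.0, ar_phi=0.5, ma_omega=0.2, fwhm=4.0)
    vol = bs.generate_noise(
        desk_template, desk_mask, params, T=120, tr=1.5, fit=True, seed=1
    )
    return vol, params


@pytest.fixture
def small_template():
    return bs.synthetic_template(dims=(16, 16, 8), voxel_size=(3.0, 3.0, 3.0), seed=3)


@pytest.fixture
def small_mask(small_template):
    return bs.compute_mask(small_template)


def full_mask(dims, hole=(0, 0, 0)):
    """All-brain mask except one voxel (BrainMask requires both classes)."""
    m = np.ones(dims, dtype=bool)
    m[hole] = False
    return bs.BrainMask(m)
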