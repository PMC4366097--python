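import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import noecest as nc
from noecest import zspec

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_phantom():
    return nc.build_phantom(nc.PhantomConfig(seed=1))


def run_chain(phantom, noise_sigma, seed):
    """Full processing chain on one simulated acquisition."""
    acq = nc.simulate_acquisition(
        phantom, nc.AcquisitionParams(noise_sigma=noise_sigma), seed=seed
    )
    z = zspec.normalize(acq.saturated, acq.m0, acq.offsets_ppm, acq.affine)
    b0 = zspec.estimate_b0(z)
    zc = zspec.correct_b0(z, b0)
    mtr = zspec.compute_mtr_asym(zc)
    return z, b0, zc, mtr


@pytest.fixture(scope="session")
def noise_free_chain(default_phantom):
    return run_chain(default_phantom, noise_sigma=0.0, seed=2)


@pytest.fixture(scope="session")
def analytic_mtr_truth(default_phantom):
    """Two-sided Lorentzian evaluation at +-10/3 ppm, percent, B0-free."""
    r = zspec.READOUT_PPM
    z = default_phantom.noise_free_z(np.array([-r, r]), shifted=False)
    return 100.0 * (z[..., 0] - z[..., 1])
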