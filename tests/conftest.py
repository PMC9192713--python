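import pytest

import cortmag as cm
from cortmag.prf import hrf_double_gamma


@pytest.fixture(scope="session")
def aperture():
    """Default bar-aperture sequence (shared: generation is deterministic)."""
    return cm.make_bar_aperture()


@pytest.fixture(scope="session")
def hrf(aperture):
    return hrf_double_gamma(dt=aperture.frame_duration)


@pytest.fixture(scope="session")
def iso_mesh():
    """Isotropic left-hemisphere mesh at default resolution."""
    return cm.make_synthetic_hemisphere(cm.MagnificationModel())


@pytest.fixture(scope="session")
def small_mesh():
    """Coarse mesh for BOLD-simulation tests."""
    return cm.make_synthetic_hemisphere(
        cm.MagnificationModel(), n_ecc_rings=8, n_angle_spokes=9,
        ecc_range=(0.5, 10.0))


@pytest.fixture(scope="session")
def default_cohort():
    return cm.make_cohort(seed=11)
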