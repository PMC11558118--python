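import numpy as np
import pytest

from ssbwrap.polymer import WLCParams
from ssbwrap.toymodel import make_toy_tetramer


@pytest.fixture(scope="session")
def wlc():
    return WLCParams()


@pytest.fixture(scope="session")
def toy():
    """One toy tetramer complex shared across the suite."""
    return make_toy_tetramer(seed=0)


def trapezoid_stretch_energy(force, n_nt, params, n_points=100_000):
    """Independent dense-grid oracle for the WLC stretch energy (k_BT)."""
    from ssbwrap.polymer import wlc_extension, wlc_force

    z_max = wlc_extension(force, params)
    z = np.linspace(0.0, z_max, n_points)
    f = wlc_force(z, params)
    contour = n_nt * params.contour_length_per_nt
    return np.trapezoid(f, z) * contour / params.kt
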