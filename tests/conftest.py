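import numpy as np
import pytest

import femtomag as fm


@pytest.fixture
def device():
    return fm.default_device()


@pytest.fixture
def reporter():
    return fm.default_reporter()


@pytest.fixture
def isolated_device():
    """Device whose reference coil is so remote it contributes nothing.

    Used where a property of the sense coil alone (symmetry, single-coil
    linearity) is under test and residual reference pickup would mask it.
    """
    from dataclasses import replace

    dev = fm.default_device()
    far = dev.reference_coil.translated(dx=10.0 - dev.reference_coil.center.x)
    return replace(dev, reference_coil=far)


@pytest.fixture
def small_strip(reporter):
    """1000 reporters in one 1 mm test line on a short strip (sampled)."""
    return fm.generate_strip(
        [{"center_x": 3e-3, "width": 1e-3, "count": 1000}],
        length=6e-3,
        reporter=reporter,
        seed=42,
    )


@pytest.fixture
def homogenized_strip(reporter):
    """1e6 reporters, homogenized test line (device-scale loading)."""
    return fm.generate_strip(
        [{"center_x": 3e-3, "width": 1e-3, "count": 10**6}],
        length=6e-3,
        reporter=reporter,
        seed=0,
        homogenized=True,
    )


def quad_flux_oracle(coil, dipole, tol=1e-10):
    """Independent quadrature of the dipole Bz over the coil rectangle.

    Written directly from the dipole field law, bypassing the package's
    flux code paths entirely.
    """
    import math

    from scipy.integrate import dblquad

    MU0 = 4e-7 * math.pi
    c = coil.center
    pos = dipole.position
    m = dipole.moment_m

    def Bz(y, x):
        rx, ry, rz = x - pos.x, y - pos.y, c.z - pos.z
        r2 = rx * rx + ry * ry + rz * rz
        r = math.sqrt(r2)
        mdotr = m.x * rx + m.y * ry + m.z * rz
        return (MU0 / (4 * math.pi)) * (3 * mdotr * rz / r2 - m.z) / (r2 * r)

    val, err = dblquad(
        Bz,
        c.x - coil.half_width_t,
        c.x + coil.half_width_t,
        c.y - coil.half_height_h,
        c.y + coil.half_height_h,
        epsabs=0.0,
        epsrel=tol,
    )
    return val
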