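"""Dipole flux through rectangular pickup coils and the differential signal.

For a z-moment dipole a standoff p under a rectangular loop of half-extents
t (x) and h (y), the normal flux admits a closed form.  The corner
primitive — the flux through [0,a] × [0,b] of the coil plane — is

    phi(a,b,p) = (mu0 m_z / 4 pi) · a b (a² + b² + 2p²)
                 / [ (a² + p²)(b² + p²) sqrt(a² + b² + p²) ] ,

and the centered full-coil flux is 4·phi(t,h,p).  Off-center dipoles are
handled by inclusion–exclusion over four signed corner terms; arbitrary
moment orientations fall back to adaptive 2-D quadrature of the dipole
field, which also serves as the independent oracle for the closed form.

Note the square root in the denominator: the flux must scale as
mu0·m/length, which fixes the final factor dimensionally.  The shape
factor alpha is geometry-only, so that phi_z = alpha·m_z with
m_z = chi·V·Ha for an induced reporter moment.

The differential readout is the induced voltage through the sense coil
minus the same through the counter-wound reference coil: with no magnetic
material, or with identical loading under both coils, the detector output
is exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate

from .device import MU0, CoilGeometry, DeviceConfig, DriveConfig, MagneticReporter, Vector3
from .magnetostatics import Dipole


class UnsupportedOrientationError(ValueError):
    """Closed form requested for a non-z moment; use rect_flux_quadrature."""


class InvalidStandoffError(ValueError):
    """Dipole lies in (or standoff does not clear) the coil plane."""


@dataclass(frozen=True)
class FluxResult:
    flux_phi_z: float  # weber
    method: str  # "closed_form" | "quadrature"
    est_error: Optional[float] = None  # weber, quadrature only


@dataclass(frozen=True)
class ShapeFactor:
    """Geometry-only coupling alpha (Wb per A·m²): phi_z = alpha · m_z."""

    alpha: float
    t: float
    h: float
    p: float


@dataclass(frozen=True)
class SignalResult:
    voltage_amplitude_eps: float  # volt
    convention: str  # "physical" | "datasheet"


def corner_flux(a: float, b: float, p: float, m_z: float) -> float:
    """Flux (Wb) of a z-moment dipole through [0,a]×[0,b] at standoff p.

    Signed: negative a or b flips the sign (the integrand is even in x
    and y).  p must be strictly positive.
    """
    if not p > 0:
        raise InvalidStandoffError(f"standoff p must be > 0 (got {p})")
    return float(_corner_flux_arr(a, b, p, m_z))


def _corner_flux_arr(a, b, p, m_z):
    # odd in a and b via the a·b factor; all other factors even
    a2, b2, p2 = np.square(a), np.square(b), np.square(p)
    return (
        (MU0 * m_z / (4.0 * np.pi))
        * a * b * (a2 + b2 + 2.0 * p2)
        / ((a2 + p2) * (b2 + p2) * np.sqrt(a2 + b2 + p2))
    )


def flux_through_coil(coil: CoilGeometry, positions: np.ndarray, m_z: np.ndarray) -> np.ndarray:
    """Closed-form flux through ``coil`` for an (n,3) array of z-moment dipoles.

    Inclusion–exclusion over the four signed corner primitives, vectorized
    over dipoles.  Dipoles in the coil plane are rejected.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    m_z = np.asarray(m_z, dtype=float)
    c = coil.center
    p = np.abs(c.z - positions[:, 2])
    if np.any(p <= 0):
        raise InvalidStandoffError("dipole lies in the coil plane")
    x1 = (c.x - coil.half_width_t) - positions[:, 0]
    x2 = (c.x + coil.half_width_t) - positions[:, 0]
    y1 = (c.y - coil.half_height_h) - positions[:, 1]
    y2 = (c.y + coil.half_height_h) - positions[:, 1]
    return (
        _corner_flux_arr(x2, y2, p, m_z)
        - _corner_flux_arr(x1, y2, p, m_z)
        - _corner_flux_arr(x2, y1, p, m_z)
        + _corner_flux_arr(x1, y1, p, m_z)
    )


def rect_flux_closed(coil: CoilGeometry, dipole: Dipole) -> FluxResult:
    """Closed-form flux of a z-moment dipole through a rectangular coil.

    Centered dipoles reduce to 4·corner_flux(t, h, p, ·); off-center ones
    use inclusion–exclusion.  Raises UnsupportedOrientationError for
    moments with x/y components (route those to rect_flux_quadrature).
    """
    m = dipole.moment_m
    scale = m.norm()
    if scale > 0.0 and max(abs(m.x), abs(m.y)) > 1e-12 * scale:
        raise UnsupportedOrientationError(
            "closed form supports z-oriented moments only; use rect_flux_quadrature"
        )
    phi = flux_through_coil(coil, dipole.position.as_array()[None, :], np.array([m.z]))
    return FluxResult(flux_phi_z=float(phi[0]), method="closed_form")


def rect_flux_quadrature(coil: CoilGeometry, dipole: Dipole, tol: float = 1e-9) -> FluxResult:
    """Adaptive 2-D quadrature of the dipole field's z-component over the coil.

    Supports arbitrary moment orientation; est_error is the quadrature's
    absolute error estimate.  This is the module's oracle for the closed
    form.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    c = coil.center
    pos = dipole.position
    if c.z == pos.z:
        raise InvalidStandoffError("dipole lies in the coil plane")
    m = dipole.moment_m.as_array()
    if not np.any(m):
        return FluxResult(0.0, "quadrature", 0.0)
    zc = c.z

    def Bz(y: float, x: float) -> float:
        rx, ry, rz = x - pos.x, y - pos.y, zc - pos.z
        r2 = rx * rx + ry * ry + rz * rz
        r = math.sqrt(r2)
        mdotr = m[0] * rx + m[1] * ry + m[2] * rz
        return (MU0 / (4.0 * math.pi)) * (3.0 * mdotr * rz / r2 - m[2]) / (r2 * r)

    val, err = integrate.dblquad(
        Bz,
        c.x - coil.half_width_t,
        c.x + coil.half_width_t,
        c.y - coil.half_height_h,
        c.y + coil.half_height_h,
        epsabs=0.0,
        epsrel=tol,
    )
    return FluxResult(flux_phi_z=float(val), method="quadrature", est_error=float(err))


def shape_factor(coil: CoilGeometry, p: float) -> ShapeFactor:
    """Geometry-only coupling alpha(t, h, p) so that phi_z = alpha·m_z."""
    if not p > 0:
        raise InvalidStandoffError(f"standoff p must be > 0 (got {p})")
    t, h = coil.half_width_t, coil.half_height_h
    alpha = (
        (MU0 / math.pi)
        * t * h * (t * t + h * h + 2.0 * p * p)
        / ((h * h + p * p) * (t * t + p * p) * math.sqrt(t * t + h * h + p * p))
    )
    return ShapeFactor(alpha=alpha, t=t, h=h, p=p)


_CONVENTION_FACTOR = {"physical": 2.0 * math.pi, "datasheet": 1.0}


def induced_voltage(
    alpha: ShapeFactor,
    drive: DriveConfig,
    reporter: MagneticReporter,
    H0: float,
    convention: str = "physical",
) -> SignalResult:
    """Voltage amplitude induced by one reporter centered under the coil.

    With Ha(t) = H0 sin(2 pi f t) and phi = alpha·chi·V·Ha, Faraday's law
    gives the amplitude 2 pi f · alpha · chi · V · H0 ("physical").  The
    "datasheet" convention drops the 2 pi (amplitude f·alpha·chi·V·H0),
    as instrument quick-reference formulas sometimes do; every
    result records which convention produced it.
    """
    if convention not in _CONVENTION_FACTOR:
        raise ValueError(f"unknown convention {convention!r}")
    amp = (
        _CONVENTION_FACTOR[convention]
        * drive.frequency_f
        * alpha.alpha
        * reporter.susceptibility_chi
        * reporter.volume_V
        * H0
    )
    return SignalResult(voltage_amplitude_eps=abs(amp), convention=convention)


def signal_from_dipoles(
    positions: np.ndarray,
    m_z: np.ndarray,
    device: DeviceConfig,
    convention: str = "physical",
) -> float:
    """Signed differential voltage from an (n,3) array of z-moment dipoles.

    Sum of per-dipole closed-form flux through the sense coil minus the
    reference coil, times the Faraday factor.  Empty input gives exactly 0.
    """
    if convention not in _CONVENTION_FACTOR:
        raise ValueError(f"unknown convention {convention!r}")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        return 0.0
    phi_s = flux_through_coil(device.sense_coil, positions, m_z)
    phi_r = flux_through_coil(device.reference_coil, positions, m_z)
    dphi = float(np.sum(phi_s) - np.sum(phi_r))
    return _CONVENTION_FACTOR[convention] * device.drive.frequency_f * dphi


def detector_signal(
    strip,
    device: DeviceConfig,
    strip_offset_x: float,
    convention: str = "physical",
) -> float:
    """Signed differential voltage for a strip translated by strip_offset_x.

    The strip's dipoles (positions in the strip frame, reporter counts as
    weights) are shifted along x by the offset; each carries the induced
    moment chi·V·Hz of its reporters.  In uniform drive mode Hz = H0
    everywhere; in biot_savart mode Hz comes from the excitation trace at
    each dipole location.
    """
    positions, weights = strip.dipoles()
    if positions.size == 0:
        return 0.0
    pos = np.array(positions, dtype=float)
    pos[:, 0] += strip_offset_x
    reporter = strip.reporter
    drive = device.drive
    if drive.mode == "uniform":
        Hz = np.full(pos.shape[0], float(drive.field_amplitude_H0))
    else:
        from .magnetostatics import trace_B_many

        trace = device.excitation
        if drive.current_amplitude is not None and drive.current_amplitude != trace.current_amplitude:
            from dataclasses import replace

            trace = replace(trace, current_amplitude=drive.current_amplitude)
        Hz = trace_B_many(trace, pos)[:, 2] / MU0
    m_z = reporter.susceptibility_chi * reporter.volume_V * Hz * np.asarray(weights, dtype=float)
    return signal_from_dipoles(pos, m_z, device, convention=convention)


def reference_coupling_ratio(device: DeviceConfig, x_line: float = 0.0) -> float:
    """|flux into reference| / |flux into sense| for a unit test dipole.

    The probe dipole sits at the strip mid-plane under x_line.  Used to
    verify (not assume) that the reference coil is far enough from the
    test line for the differential readout to represent the sense coil
    alone.
    """
    z = device.strip_thickness / 2.0
    pos = np.array([[x_line, 0.0, z]])
    m = np.array([1.0])
    phi_s = flux_through_coil(device.sense_coil, pos, m)[0]
    phi_r = flux_through_coil(device.reference_coil, pos, m)[0]
    return abs(phi_r) / abs(phi_s)
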