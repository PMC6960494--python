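"""Point-dipole fields and the Biot–Savart field of a finite rectangular trace.

The flux density of a point dipole with moment m at separation r is

    B = (mu0 / 4 pi) · (3 (m·r̂) r̂ − m) / r³ ,

which for m = m ẑ gives Bz = (mu0 m / 4 pi)(3 z² − r²)/r⁵.  A reporter in
the linear (unsaturated) regime acquires the induced moment m = chi·V·H.

The excitation trace field is evaluated by discretizing the conductor
cross-section into straight filaments and summing the exact finite-segment
Biot–Savart field of each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .device import MU0, ExcitationTrace, MagneticReporter, Vector3


class SingularPointError(ValueError):
    """Field requested exactly at a source location."""


class InsideConductorError(ValueError):
    """Field requested inside the conductor volume."""


@dataclass(frozen=True)
class Dipole:
    """A point magnetic dipole: position (m) and moment (A·m²)."""

    position: Vector3 = field(default_factory=lambda: Vector3(0.0, 0.0, 0.0))
    moment_m: Vector3 = field(default_factory=lambda: Vector3(0.0, 0.0, 0.0))


@dataclass(frozen=True)
class FieldSample:
    point: Vector3
    B: Vector3  # tesla


def dipole_B(dipole: Dipole, point: Vector3) -> Vector3:
    """Flux density (tesla) of a point dipole at ``point``.

    Raises SingularPointError at the dipole location, where the field
    diverges.
    """
    r = point.as_array() - dipole.position.as_array()
    r2 = float(r @ r)
    if r2 == 0.0:
        raise SingularPointError("field evaluation at the dipole location")
    m = dipole.moment_m.as_array()
    rn = np.sqrt(r2)
    rhat = r / rn
    B = (MU0 / (4.0 * np.pi)) * (3.0 * (m @ rhat) * rhat - m) / rn**3
    return Vector3.from_array(B)


def induced_moment(reporter: MagneticReporter, H_local: Vector3) -> Vector3:
    """Induced moment m = chi·V·H of an unsaturated reporter (A·m²)."""
    s = reporter.susceptibility_chi * reporter.volume_V
    return Vector3(s * H_local.x, s * H_local.y, s * H_local.z)


def _segment_B(a: np.ndarray, b: np.ndarray, current: float, points: np.ndarray) -> np.ndarray:
    """Biot–Savart field of a straight segment a->b at an array of points.

    Exact finite-segment closed form; ``points`` has shape (n, 3), the
    result likewise.  On-axis points (where the perpendicular distance
    vanishes) get a zero field, the correct limit off the segment ends.
    """
    u = b - a
    L = np.linalg.norm(u)
    uhat = u / L
    w = points - a  # (n,3)
    proj = w @ uhat  # (n,)
    perp = w - proj[:, None] * uhat
    d = np.linalg.norm(perp, axis=1)
    out = np.zeros_like(points)
    ok = d > 0
    if np.any(ok):
        dk, pk = d[ok], proj[ok]
        s1 = pk / np.hypot(dk, pk)
        s2 = (pk - L) / np.hypot(dk, pk - L)
        mag = MU0 * current / (4.0 * np.pi * dk) * (s1 - s2)
        direction = np.cross(np.broadcast_to(uhat, perp[ok].shape), perp[ok] / dk[:, None])
        out[ok] = mag[:, None] * direction
    return out


def trace_B(trace: ExcitationTrace, point: Vector3) -> Vector3:
    """Field (tesla) of the excitation trace at ``point``.

    The rectangular cross-section (width × thickness) is split into
    n_filaments × n_filaments filaments each carrying I/n², and the exact
    finite-segment field of every filament is summed.  Raises
    InsideConductorError for points inside the conductor volume.
    """
    return Vector3.from_array(trace_B_many(trace, point.as_array()[None, :])[0])


def trace_B_many(trace: ExcitationTrace, points: np.ndarray) -> np.ndarray:
    """Vectorized trace_B over an (n, 3) array of points."""
    points = np.asarray(points, dtype=float)
    c = trace.center.as_array()
    rel = points - c
    inside = (
        (np.abs(rel[:, 0]) < trace.length / 2)
        & (np.abs(rel[:, 1]) < trace.width / 2)
        & (np.abs(rel[:, 2]) < trace.thickness / 2)
    )
    if np.any(inside):
        raise InsideConductorError("field evaluation inside the excitation trace")
    n = trace.n_filaments
    # filament positions at cell centers across width (y) and thickness (z)
    ys = c[1] + ((np.arange(n) + 0.5) / n - 0.5) * trace.width
    zs = c[2] + ((np.arange(n) + 0.5) / n - 0.5) * trace.thickness
    I_fil = trace.current_amplitude / (n * n)
    B = np.zeros_like(points)
    x0, x1 = c[0] - trace.length / 2, c[0] + trace.length / 2
    for y in ys:
        for z in zs:
            a = np.array([x0, y, z])
            b = np.array([x1, y, z])
            B += _segment_B(a, b, I_fil, points)
    return B
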