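"""Device geometry, units and configuration types.

Single home for every physical symbol of the transducer model: the
rectangular pickup coils (half-extents t, h and plane standoff p), the
excitation trace, the drive, and the superparamagnetic reporter
(volume V, susceptibility chi, saturation magnetization Ms, density rho).

Internal unit system is SI (m, A/m, T, Wb, V, s).  The bead-counting
arithmetic is stated by its instrument in CGS-style units (emu, emu/g,
g/cm^3, mm^3); those enter at the API boundary through the explicit
converters below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

MU0 = 4e-7 * math.pi  # vacuum permeability, T·m/A

#: 1 emu = 1e-3 A·m² (CGS electromagnetic unit of magnetic moment)
AM2_PER_EMU = 1e-3

MM3_TO_M3 = 1e-9
MM3_TO_CM3 = 1e-3
MM = 1e-3


def emu_to_si(moment_emu: float) -> float:
    """Convert a magnetic moment from emu to A·m² (1 emu = 1e-3 A·m²)."""
    return moment_emu * AM2_PER_EMU


def si_to_emu(moment_am2: float) -> float:
    """Convert a magnetic moment from A·m² to emu."""
    return moment_am2 / AM2_PER_EMU


@dataclass(frozen=True)
class Vector3:
    """A point or vector in the right-handed lab frame (metres or field units)."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a) -> "Vector3":
        a = np.asarray(a, dtype=float)
        return Vector3(float(a[0]), float(a[1]), float(a[2]))

    def norm(self) -> float:
        return math.sqrt(self.x**2 + self.y**2 + self.z**2)

    def __add__(self, other: "Vector3") -> "Vector3":
        return Vector3(self.x + other.x, self.y + other.y, self.z + other.z)

    def __sub__(self, other: "Vector3") -> "Vector3":
        return Vector3(self.x - other.x, self.y - other.y, self.z - other.z)


@dataclass(frozen=True)
class CoilGeometry:
    """Rectangular pickup loop spanning x in [cx-t, cx+t], y in [cy-h, cy+h].

    The loop lies in a plane parallel to xy at z = center.z; its normal is
    fixed to +z.  ``half_width_t`` is the half-extent along the strip
    translation axis (x), ``half_height_h`` across it (y).  The per-dipole
    standoff p is |center.z - z_dipole|.
    """

    half_width_t: float
    half_height_h: float
    center: Vector3 = field(default_factory=lambda: Vector3(0.0, 0.0, 0.0))

    def translated(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "CoilGeometry":
        c = self.center
        return replace(self, center=Vector3(c.x + dx, c.y + dy, c.z + dz))


@dataclass(frozen=True)
class ExcitationTrace:
    """Straight rectangular-cross-section conductor carrying the drive current.

    Runs along x through ``center``; ``width`` is its y extent and
    ``thickness`` its z extent.  For field evaluation the cross-section is
    discretized into n_filaments × n_filaments straight filaments.
    """

    length: float = 10.0 * MM
    width: float = 1.0 * MM
    thickness: float = 0.035 * MM
    center: Vector3 = field(default_factory=lambda: Vector3(0.0, 0.0, -0.5 * MM))
    current_amplitude: float = 0.1
    n_filaments: int = 8


@dataclass(frozen=True)
class DriveConfig:
    """Excitation drive: a sinusoidal field/current at frequency f.

    ``uniform`` mode applies a spatially uniform H0 ẑ at every reporter
    (the analytic model); ``biot_savart`` mode derives the local field from
    the excitation trace instead.
    """

    frequency_f: float = 90e6
    mode: str = "uniform"  # "uniform" | "biot_savart"
    # 2.4e4 A/m ~ 300 Oe: the excitation scale this sensor family drives
    # reporters at, still linear for chi=0.17 (M/Msat ~ 5%); the true coil
    # current is not known, so this is a free config parameter
    field_amplitude_H0: Optional[float] = 2.4e4  # A/m, uniform mode
    current_amplitude: Optional[float] = None  # A, biot_savart mode


@dataclass(frozen=True)
class MagneticReporter:
    """One superparamagnetic reporter species.

    In the linear regime a reporter acquires moment m = chi·V·H.  The
    bead-counting identity N = MT/(Ms·rho·V) uses Ms in emu/g, rho in
    g/cm³ and V in cm³, so those fields keep their instrument units.
    """

    volume_V: float = 4.2e-12 * MM3_TO_M3  # m³
    susceptibility_chi: float = 0.17
    saturation_Ms: float = 40.0  # emu/g
    density_rho: float = 2.0  # g/cm³
    diameter: Optional[float] = None  # m, optional; must be consistent with V

    @property
    def volume_mm3(self) -> float:
        return self.volume_V / MM3_TO_M3

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 * MM3_TO_CM3

    @property
    def mass_g(self) -> float:
        """Mass of one reporter in grams (rho g/cm³ × V cm³)."""
        return self.density_rho * self.volume_cm3

    @property
    def saturation_moment_emu(self) -> float:
        """Saturation moment of a single reporter, emu (Ms·rho·V)."""
        return self.saturation_Ms * self.mass_g


@dataclass(frozen=True)
class DeviceConfig:
    """Full transducer description: two congruent pickup coils, counter-wound
    (sense minus reference), an excitation trace, and the drive."""

    sense_coil: CoilGeometry = field(
        default_factory=lambda: CoilGeometry(0.125 * MM, 5.0 * MM, Vector3(0.0, 0.0, 0.3 * MM))
    )
    reference_coil: CoilGeometry = field(
        default_factory=lambda: CoilGeometry(0.125 * MM, 5.0 * MM, Vector3(10.0 * MM, 0.0, 0.3 * MM))
    )
    excitation: ExcitationTrace = field(default_factory=ExcitationTrace)
    drive: DriveConfig = field(default_factory=DriveConfig)
    gap: float = 0.3 * MM
    strip_thickness: float = 0.2 * MM


def default_device() -> DeviceConfig:
    """Device with the published prototype geometry and drive frequency."""
    return DeviceConfig()


def default_reporter() -> MagneticReporter:
    """200 nm polymer-encapsulated iron-oxide reporter bead."""
    return MagneticReporter()


def _finite(*vals) -> bool:
    return all(math.isfinite(v) for v in vals)


def validate_device(config: DeviceConfig) -> list[str]:
    """Check every invariant of a device configuration.

    Returns a list of human-readable violations (empty iff valid); each
    entry names the offending field and the rule it breaks.  Violations are
    data, not exceptions, so a caller can report all of them at once.
    """
    v: list[str] = []
    sc, rc = config.sense_coil, config.reference_coil
    for name, coil in (("sense_coil", sc), ("reference_coil", rc)):
        if not coil.half_width_t > 0:
            v.append(f"{name}.half_width_t: must be > 0 (got {coil.half_width_t})")
        if not coil.half_height_h > 0:
            v.append(f"{name}.half_height_h: must be > 0 (got {coil.half_height_h})")
        if not _finite(coil.center.x, coil.center.y, coil.center.z):
            v.append(f"{name}.center: components must be finite")
    if (sc.half_width_t, sc.half_height_h) != (rc.half_width_t, rc.half_height_h):
        v.append(
            "sense_coil/reference_coil: coils must be congruent (same t, h) "
            "for differential null balance"
        )
    ex = config.excitation
    for fname in ("length", "width", "thickness"):
        if not getattr(ex, fname) > 0:
            v.append(f"excitation.{fname}: must be > 0 (got {getattr(ex, fname)})")
    if ex.n_filaments < 1:
        v.append(f"excitation.n_filaments: must be >= 1 (got {ex.n_filaments})")
    dr = config.drive
    if not dr.frequency_f > 0:
        v.append(f"drive.frequency_f: must be > 0 (got {dr.frequency_f})")
    if dr.mode not in ("uniform", "biot_savart"):
        v.append(f"drive.mode: must be 'uniform' or 'biot_savart' (got {dr.mode!r})")
    if dr.mode == "uniform" and dr.field_amplitude_H0 is None:
        v.append("drive.field_amplitude_H0: required in uniform mode")
    if dr.mode == "biot_savart" and dr.current_amplitude is None:
        v.append("drive.current_amplitude: required in biot_savart mode")
    if not config.gap > config.strip_thickness:
        v.append(
            f"gap: must exceed strip_thickness ({config.gap} <= {config.strip_thickness})"
        )
    return v


def validate_reporter(reporter: MagneticReporter) -> list[str]:
    """Invariant check for a reporter species; same contract as validate_device."""
    v: list[str] = []
    if not reporter.volume_V > 0:
        v.append(f"reporter.volume_V: must be > 0 (got {reporter.volume_V})")
    if reporter.susceptibility_chi < 0:
        v.append(f"reporter.susceptibility_chi: must be >= 0 (got {reporter.susceptibility_chi})")
    if not reporter.saturation_Ms > 0:
        v.append(f"reporter.saturation_Ms: must be > 0 (got {reporter.saturation_Ms})")
    if not reporter.density_rho > 0:
        v.append(f"reporter.density_rho: must be > 0 (got {reporter.density_rho})")
    if reporter.diameter is not None and reporter.volume_V > 0:
        v_sphere = math.pi / 6.0 * reporter.diameter**3
        if abs(v_sphere - reporter.volume_V) / reporter.volume_V >= 1e-6:
            v.append(
                "reporter.diameter: pi/6·d^3 inconsistent with volume_V "
                f"(relative mismatch {abs(v_sphere - reporter.volume_V) / reporter.volume_V:.3g})"
            )
    return v
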