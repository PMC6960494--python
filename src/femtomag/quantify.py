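"""Reporter counting, susceptibility extraction, calibration and dose response.

The bead count follows from saturation magnetometry:

    N = MT / (Ms · rho · V) ,

with MT the saturation moment of the line (emu), Ms the reporter mass
magnetization at saturation (emu/g), rho its density (g/cm³) and V its
volume (cm³).  The arithmetic is done in these CGS-style units exactly as
the instrument states them; SI entry points convert first.  With the
defaults (Ms = 40 emu/g, rho = 2.0 g/cm³, V = 4.2e-12 mm³) one bead
saturates at 3.36e-13 emu.

The low-field volume susceptibility chi is the slope of the M–H loop in
its linear region; the scan-voltage-to-count calibration is a
through-origin regression, since zero beads give zero differential signal
by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import constants

from .device import MagneticReporter
from .scan import PeakCall, ScanProfile, extract_peak


class InsufficientDataError(ValueError):
    """Too few points for the requested fit."""


@dataclass
class MHLoop:
    """Applied field vs. moment table from a magnetometer sweep."""

    H: np.ndarray
    M: np.ndarray
    unit_H: str = "Oe"
    unit_M: str = "emu"
    branch: Optional[np.ndarray] = None  # e.g. "up"/"down" labels

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if len(self.H) != len(self.M):
            raise ValueError("H and M must have equal length")
        if self.branch is not None:
            self.branch = np.asarray(self.branch)
            if len(self.branch) != len(self.H):
                raise ValueError("branch labels must match H length")


@dataclass(frozen=True)
class QuantResult:
    bead_count_N: float
    total_moment_MT: float  # emu
    method: str  # "agfm" | "femtomag_calibrated"


@dataclass(frozen=True)
class CalibrationResult:
    volts_per_bead: float
    residual_rms: float  # V
    n_points: int


def beads_from_magnetization(MT_emu: float, reporter: MagneticReporter) -> QuantResult:
    """Bead count N = MT/(Ms·rho·V) from a saturation moment in emu."""
    if MT_emu < 0:
        raise ValueError(f"saturation moment must be >= 0 (got {MT_emu})")
    N = MT_emu / reporter.saturation_moment_emu
    return QuantResult(bead_count_N=N, total_moment_MT=MT_emu, method="agfm")


def magnetization_from_beads(N: float, reporter: MagneticReporter) -> float:
    """Inverse of beads_from_magnetization: saturation moment (emu) of N beads."""
    return N * reporter.saturation_moment_emu


def estimate_saturation(loop: MHLoop, top_fraction: float = 0.1) -> float:
    """Saturation plateau estimate: mean |M| over the top decile of |H|."""
    absH = np.abs(loop.H)
    cut = np.quantile(absH, 1.0 - top_fraction)
    return float(np.mean(np.abs(loop.M[absH >= cut])))


def susceptibility_from_mh(loop: MHLoop, fit_fraction: float = 0.3) -> float:
    """Low-field slope of the M–H loop, in the loop's declared units.

    Fits a least-squares line to the points with |M| <= fit_fraction of the
    saturation plateau, per branch when branch labels are present, and
    averages the branch slopes.  Raises InsufficientDataError when fewer
    than 5 points fall in the fit window.
    """
    Ms = estimate_saturation(loop)
    mask = np.abs(loop.M) <= fit_fraction * Ms if Ms > 0 else np.ones(len(loop.M), dtype=bool)
    if mask.sum() < 5:
        raise InsufficientDataError(
            f"only {int(mask.sum())} points with |M| <= {fit_fraction}·Ms; need >= 5"
        )
    if loop.branch is not None:
        slopes = []
        for lbl in pd.unique(loop.branch):
            sel = mask & (loop.branch == lbl)
            if sel.sum() >= 2:
                slopes.append(np.polyfit(loop.H[sel], loop.M[sel], 1)[0])
        if not slopes:
            raise InsufficientDataError("no branch has >= 2 points in the fit window")
        return float(np.mean(slopes))
    return float(np.polyfit(loop.H[mask], loop.M[mask], 1)[0])


def _peak_voltage(item) -> float:
    if isinstance(item, ScanProfile):
        return extract_peak(item).peak_voltage
    if isinstance(item, PeakCall):
        return item.peak_voltage
    return float(item)


def calibrate_voltage_to_count(profiles: Sequence[tuple]) -> CalibrationResult:
    """Zero-intercept regression of peak voltage on known bead count.

    ``profiles`` is a sequence of (ScanProfile | PeakCall | voltage, N)
    pairs with at least two distinct N.  Returns volts per bead and the
    residual RMS of the fit.
    """
    if len(profiles) < 2:
        raise InsufficientDataError("calibration needs >= 2 points")
    v = np.array([_peak_voltage(p) for p, _ in profiles], dtype=float)
    N = np.array([n for _, n in profiles], dtype=float)
    if np.all(N == N[0]):
        raise InsufficientDataError("calibration points must span distinct bead counts")
    factor = float(np.dot(v, N) / np.dot(N, N))
    resid = v - factor * N
    return CalibrationResult(
        volts_per_bead=factor,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=len(profiles),
    )


def count_from_voltage(peak_voltage: float, calibration: CalibrationResult) -> QuantResult:
    """Bead count from a peak voltage using a prior calibration."""
    N = peak_voltage / calibration.volts_per_bead
    return QuantResult(bead_count_N=N, total_moment_MT=math.nan, method="femtomag_calibrated")


def molecules_in_sample(
    concentration_ng_per_mL: float, volume_uL: float, molar_mass_g_per_mol: float
) -> float:
    """Analyte molecule count in a sample of given concentration and volume.

    The molar mass is a required input; there is no default.
    """
    if molar_mass_g_per_mol is None or not molar_mass_g_per_mol > 0:
        raise ValueError("molar mass (g/mol) is required and must be > 0")
    if concentration_ng_per_mL < 0 or volume_uL < 0:
        raise ValueError("concentration and volume must be >= 0")
    mass_g = concentration_ng_per_mL * 1e-9 * volume_uL * 1e-3
    return mass_g / molar_mass_g_per_mol * constants.Avogadro


def molecules_per_bead(molecules: float, beads: float) -> float:
    """Analyte molecules in the sample per reporter captured in the line."""
    if not beads > 0:
        raise ValueError(f"bead count must be > 0 (got {beads})")
    return molecules / beads


def dose_response_table(points: Sequence[dict]) -> tuple[pd.DataFrame, bool]:
    """Per-concentration molecules, beads and their ratio, plus monotonicity.

    Each point supplies either precomputed ``molecules`` or the triple
    (concentration, sample_volume_uL, molar_mass) to compute them, and
    ``beads``.  Rows are sorted by concentration; the flag is True iff the
    molecules-per-bead ratio is nondecreasing with concentration.
    """
    if len(points) < 2:
        raise InsufficientDataError("dose-response needs >= 2 concentrations")
    rows = []
    for pt in points:
        conc = float(pt["concentration"])
        beads = float(pt["beads"])
        if "molecules" in pt:
            mol = float(pt["molecules"])
        else:
            mol = molecules_in_sample(conc, float(pt["sample_volume_uL"]), float(pt["molar_mass"]))
        rows.append(
            {
                "concentration_ng_per_mL": conc,
                "molecules": mol,
                "beads": beads,
                "ratio": molecules_per_bead(mol, beads),
            }
        )
    df = pd.DataFrame(rows).sort_values("concentration_ng_per_mL").reset_index(drop=True)
    monotone = bool(np.all(np.diff(df["ratio"].to_numpy()) >= 0))
    return df, monotone


def synthetic_linear_loop(chi: float, Hmax: float = 100.0, n: int = 101) -> MHLoop:
    """Perfectly linear anhysteretic loop M = chi·H (synthetic fixture)."""
    H = np.linspace(-Hmax, Hmax, n)
    return MHLoop(H=H, M=chi * H)


def synthetic_langevin_loop(
    chi0: float,
    Msat: float,
    Hmax: float,
    n: int = 201,
    noise: float = 0.0,
    seed: int = 0,
    branches: bool = True,
) -> MHLoop:
    """Langevin-shaped anhysteretic loop with known initial slope (synthetic).

    M(H) = Msat·L(3·chi0·H/Msat) with L(x) = coth x − 1/x, so dM/dH at
    H = 0 equals chi0 exactly.  Optional Gaussian noise on M; two labelled
    branches (identical sweeps, as for a superparamagnet with no
    remanence).
    """
    H = np.linspace(-Hmax, Hmax, n)
    xi = 3.0 * chi0 * H / Msat
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.where(np.abs(xi) < 1e-6, xi / 3.0, 1.0 / np.tanh(xi) - 1.0 / np.where(xi == 0, 1, xi))
    M = Msat * L
    if branches:
        H = np.concatenate([H, H[::-1]])
        M = np.concatenate([M, M[::-1]])
        branch = np.array(["up"] * n + ["down"] * n)
    else:
        branch = None
    if noise > 0:
        rng = np.random.default_rng(seed)
        M = M + rng.normal(0.0, noise, len(M))
    return MHLoop(H=H, M=M, branch=branch)
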