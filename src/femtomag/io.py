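"""Configuration loading, CSV/JSON formats and run manifests.

Disk formats use the working units of the instrument: millimetres for
geometry and µV for voltages; everything converts to SI on load.  All
writers emit 12 significant digits so write→read round-trips are lossless
at that precision, with deterministic column order.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .device import (
    MM,
    CoilGeometry,
    DeviceConfig,
    DriveConfig,
    ExcitationTrace,
    MagneticReporter,
    Vector3,
    validate_device,
    validate_reporter,
)
from .quantify import MHLoop
from .scan import ReporterLine, ScanProfile, StripModel


class ConfigError(ValueError):
    """Schema violation in a config file (unknown key, bad value)."""


class FormatError(ValueError):
    """Malformed data file (missing column, ragged rows, unit mismatch)."""


def _check_keys(mapping: dict, allowed: set, path: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown config key {path}.{key}")


def _coil_from(cfg: dict, base: CoilGeometry, path: str) -> CoilGeometry:
    _check_keys(cfg, {"t_mm", "h_mm", "center_mm"}, path)
    t = cfg.get("t_mm", base.half_width_t / MM) * MM
    h = cfg.get("h_mm", base.half_height_h / MM) * MM
    c = cfg.get("center_mm")
    center = Vector3(*(x * MM for x in c)) if c is not None else base.center
    return CoilGeometry(half_width_t=t, half_height_h=h, center=center)


def load_config(path) -> tuple[DeviceConfig, MagneticReporter]:
    """Load and validate a device+reporter YAML config.

    An empty file yields the full default device; unknown keys are hard
    errors naming the key path; invariant violations are reported together.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(data, {"device", "reporter"}, "")
    dev_cfg = data.get("device", {}) or {}
    rep_cfg = data.get("reporter", {}) or {}
    _check_keys(
        dev_cfg,
        {"sense_coil", "reference_coil", "excitation", "drive", "gap_mm", "strip_thickness_mm"},
        "device",
    )
    base = DeviceConfig()
    sense = _coil_from(dev_cfg.get("sense_coil", {}) or {}, base.sense_coil, "device.sense_coil")
    ref = _coil_from(
        dev_cfg.get("reference_coil", {}) or {}, base.reference_coil, "device.reference_coil"
    )
    ex_cfg = dev_cfg.get("excitation", {}) or {}
    _check_keys(
        ex_cfg,
        {"length_mm", "width_mm", "thickness_mm", "center_mm", "current_A", "n_filaments"},
        "device.excitation",
    )
    bex = base.excitation
    ex_center = ex_cfg.get("center_mm")
    excitation = ExcitationTrace(
        length=ex_cfg.get("length_mm", bex.length / MM) * MM,
        width=ex_cfg.get("width_mm", bex.width / MM) * MM,
        thickness=ex_cfg.get("thickness_mm", bex.thickness / MM) * MM,
        center=Vector3(*(x * MM for x in ex_center)) if ex_center is not None else bex.center,
        current_amplitude=ex_cfg.get("current_A", bex.current_amplitude),
        n_filaments=int(ex_cfg.get("n_filaments", bex.n_filaments)),
    )
    dr_cfg = dev_cfg.get("drive", {}) or {}
    _check_keys(dr_cfg, {"frequency_hz", "mode", "H0_A_per_m", "current_A"}, "device.drive")
    bdr = base.drive
    drive = DriveConfig(
        frequency_f=dr_cfg.get("frequency_hz", bdr.frequency_f),
        mode=dr_cfg.get("mode", bdr.mode),
        field_amplitude_H0=dr_cfg.get("H0_A_per_m", bdr.field_amplitude_H0),
        current_amplitude=dr_cfg.get("current_A", bdr.current_amplitude),
    )
    device = DeviceConfig(
        sense_coil=sense,
        reference_coil=ref,
        excitation=excitation,
        drive=drive,
        gap=dev_cfg.get("gap_mm", base.gap / MM) * MM,
        strip_thickness=dev_cfg.get("strip_thickness_mm", base.strip_thickness / MM) * MM,
    )
    _check_keys(rep_cfg, {"V_mm3", "chi", "Ms_emu_per_g", "rho_g_per_cm3", "diameter_nm"}, "reporter")
    brep = MagneticReporter()
    reporter = MagneticReporter(
        volume_V=rep_cfg.get("V_mm3", brep.volume_mm3) * 1e-9,
        susceptibility_chi=rep_cfg.get("chi", brep.susceptibility_chi),
        saturation_Ms=rep_cfg.get("Ms_emu_per_g", brep.saturation_Ms),
        density_rho=rep_cfg.get("rho_g_per_cm3", brep.density_rho),
        diameter=rep_cfg.get("diameter_nm", None) and rep_cfg["diameter_nm"] * 1e-9,
    )
    violations = validate_device(device) + validate_reporter(reporter)
    if violations:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(violations))
    return device, reporter


# ---------------------------------------------------------------- profiles

_PROFILE_COLUMNS = ["position_mm", "time_s", "voltage_uV"]


def write_scan_profile(profile: ScanProfile, path) -> None:
    """ScanProfile → CSV (position_mm, time_s, voltage_uV; 12 sig digits)."""
    df = pd.DataFrame(
        {
            "position_mm": profile.positions / MM,
            "time_s": profile.times,
            "voltage_uV": profile.voltages * 1e6,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_scan_profile(path) -> ScanProfile:
    """CSV → ScanProfile; velocity and sample period are recovered from the
    position/time columns (noise_rms is unknown on disk and set to nan)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse scan profile {path}: {exc}") from exc
    missing = [c for c in _PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"scan profile {path} missing column(s): {', '.join(missing)}")
    if df[_PROFILE_COLUMNS].isna().any().any():
        raise FormatError(f"scan profile {path} has missing values (ragged rows?)")
    times = df["time_s"].to_numpy()
    positions = df["position_mm"].to_numpy() * MM
    dt = float(np.median(np.diff(times))) if len(times) > 1 else float("nan")
    vel = float(np.median(np.diff(positions) / np.diff(times))) if len(times) > 1 else float("nan")
    return ScanProfile(
        positions=positions,
        times=times,
        voltages=df["voltage_uV"].to_numpy() * 1e-6,
        velocity=vel,
        sample_period=dt,
        noise_rms=float("nan"),
    )


# ------------------------------------------------------------------ strips


def write_strip(strip: StripModel, path) -> None:
    """StripModel → JSON (geometry in mm; dipoles regenerate from the seed)."""
    doc = {
        "length_mm": strip.length / MM,
        "width_mm": strip.width / MM,
        "thickness_mm": strip.thickness / MM,
        "background_density_per_m3": strip.background_density,
        "homogenized": strip.homogenized,
        "seed": strip.seed,
        "lines": [
            {
                "center_x_mm": ln.center_x / MM,
                "width_mm": ln.width / MM,
                "count": ln.count,
                "profile": ln.profile,
            }
            for ln in strip.lines
        ],
        "reporter": {
            "V_mm3": strip.reporter.volume_mm3,
            "chi": strip.reporter.susceptibility_chi,
            "Ms_emu_per_g": strip.reporter.saturation_Ms,
            "rho_g_per_cm3": strip.reporter.density_rho,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_strip(path) -> StripModel:
    doc = json.loads(Path(path).read_text())
    required = {"length_mm", "width_mm", "thickness_mm", "lines", "reporter", "seed"}
    missing = required - doc.keys()
    if missing:
        raise FormatError(f"strip file {path} missing key(s): {', '.join(sorted(missing))}")
    rep = doc["reporter"]
    reporter = MagneticReporter(
        volume_V=rep["V_mm3"] * 1e-9,
        susceptibility_chi=rep["chi"],
        saturation_Ms=rep["Ms_emu_per_g"],
        density_rho=rep["rho_g_per_cm3"],
    )
    lines = [
        ReporterLine(
            center_x=ln["center_x_mm"] * MM,
            width=ln["width_mm"] * MM,
            count=int(ln["count"]),
            profile=ln.get("profile", "uniform"),
        )
        for ln in doc["lines"]
    ]
    return StripModel(
        length=doc["length_mm"] * MM,
        width=doc["width_mm"] * MM,
        thickness=doc["thickness_mm"] * MM,
        lines=lines,
        background_density=doc.get("background_density_per_m3", 0.0),
        reporter=reporter,
        seed=int(doc["seed"]),
        homogenized=bool(doc.get("homogenized", False)),
    )


# ---------------------------------------------------------------- M–H loops


def write_mh_loop(loop: MHLoop, path) -> None:
    """MHLoop → CSV (H, M, unit_H, unit_M; unit columns constant per file)."""
    df = pd.DataFrame(
        {
            "H": loop.H,
            "M": loop.M,
            "unit_H": loop.unit_H,
            "unit_M": loop.unit_M,
        }
    )
    if loop.branch is not None:
        df["branch"] = loop.branch
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_mh_loop(path) -> MHLoop:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse M–H file {path}: {exc}") from exc
    for col in ("H", "M", "unit_H", "unit_M"):
        if col not in df.columns:
            raise FormatError(f"M–H file {path} missing column {col}")
    for col in ("unit_H", "unit_M"):
        if df[col].nunique() != 1:
            raise FormatError(f"M–H file {path}: {col} must be constant per file")
    return MHLoop(
        H=df["H"].to_numpy(),
        M=df["M"].to_numpy(),
        unit_H=str(df["unit_H"].iloc[0]),
        unit_M=str(df["unit_M"].iloc[0]),
        branch=df["branch"].to_numpy() if "branch" in df.columns else None,
    )


def write_dose_response(df: pd.DataFrame, path) -> None:
    cols = ["concentration_ng_per_mL", "molecules", "beads", "ratio"]
    df[cols].to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


# ----------------------------------------------------------------- manifest


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    seed: Optional[int]
    tool_version: str
    timestamp: str
    inputs: dict  # path -> sha256
    outputs: list


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir, command: str, seed: Optional[int], inputs: list, outputs: list
) -> Path:
    manifest = RunManifest(
        command=command,
        seed=seed,
        tool_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        inputs={str(p): file_sha256(p) for p in inputs if Path(p).exists()},
        outputs=[str(p) for p in outputs],
    )
    path = Path(out_dir) / f"{command.replace(' ', '_')}.manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return path
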