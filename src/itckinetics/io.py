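"""Readers/writers for the package's delimited-text formats.

All files share one dialect: an optional block of ``#``-prefixed header lines
carrying ``key: value`` metadata, followed by a delimited table whose
delimiter is auto-detected among comma and tab.  Units are declared in the
header (``# unit: time=s power=ucal/s``) and converted to canonical units on
load; files written by this module are always in canonical units.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import units
from .core import (
    AssayConfig,
    CellConfig,
    InjectionSchedule,
    RateCurve,
    Thermogram,
)
from .exceptions import ParseError, ValidationError

__all__ = [
    "read_thermogram",
    "write_thermogram",
    "read_injection_schedule",
    "write_injection_schedule",
    "read_rate_curve",
    "write_rate_curve",
    "read_absorbance_trace",
    "write_absorbance_trace",
    "load_config",
    "packaged_schedule_path",
]

_DATA_DIR = Path(__file__).parent / "data"


def packaged_schedule_path(name: str) -> Path:
    """Path of a packaged injection-schedule fixture (``single_lsa`` or ``multi_lsa``)."""
    path = _DATA_DIR / f"{name}.csv"
    if not path.exists():
        known = sorted(p.stem for p in _DATA_DIR.glob("*.csv"))
        raise ValidationError(f"unknown packaged schedule {name!r}; available: {known}")
    return path


def _split_header(text: str) -> tuple[dict, str]:
    """Separate ``# key: value`` header lines from the table body."""
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            content = stripped.lstrip("#").strip()
            if ":" in content:
                key, _, value = content.partition(":")
                meta[key.strip()] = value.strip()
        elif stripped:
            body_lines.append(line)
    return meta, "\n".join(body_lines)


def _read_table(body: str, path) -> pd.DataFrame:
    if not body.strip():
        raise ParseError(f"{path}: file contains no table rows")
    first = body.splitlines()[0]
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    try:
        df = pd.read_csv(_io.StringIO(body), sep=sep, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: could not parse table ({exc})") from exc
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, needed: list[str], path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def _parse_unit_header(meta: dict, path) -> dict:
    """Parse ``# unit: time=s power=ucal/s`` into a dict."""
    if "unit" not in meta:
        raise ParseError(
            f"{path}: mandatory '# unit:' header line is absent "
            "(e.g. '# unit: time=s power=ucal/s')"
        )
    out = {}
    for token in meta["unit"].replace(",", " ").split():
        if "=" not in token:
            raise ParseError(f"{path}: malformed unit token {token!r}")
        k, _, v = token.partition("=")
        out[k.strip()] = v.strip()
    return out


def read_thermogram(path, dialect: dict | None = None) -> Thermogram:
    """Read a thermogram table.

    Expected columns ``time_s`` and ``power_ucal_per_s`` (names fixed; actual
    units come from the mandatory ``# unit:`` header and are converted to
    s and μcal/s on load).  Optional headers: ``# temperature_C:``,
    ``# label:``, ``# sample_interval_s:``.
    """
    path = Path(path)
    meta, body = _split_header(path.read_text())
    udecl = _parse_unit_header(meta, path)
    df = _read_table(body, path)
    _require_columns(df, ["time_s", "power_ucal_per_s"], path)

    time = df["time_s"].to_numpy(dtype=float)
    power = df["power_ucal_per_s"].to_numpy(dtype=float)
    time = units.convert(time, udecl.get("time", "s"), units.TIME_TO_S, "time")
    power = units.convert(
        power, udecl.get("power", "ucal/s"), units.POWER_TO_UCAL_S, "power"
    )

    steps = np.diff(time)
    bad = np.flatnonzero(steps <= 0)
    if bad.size:
        # +2: one for 0-based step index -> row, one for the header row.
        raise ParseError(
            f"{path}: time not strictly increasing at data row {int(bad[0]) + 2} "
            f"(t={time[bad[0] + 1]:g} s follows t={time[bad[0]]:g} s)"
        )
    if "sample_interval_s" in meta:
        interval = float(meta["sample_interval_s"])
    else:
        interval = float(np.median(steps))
    try:
        return Thermogram(
            time=time,
            power=power,
            sample_interval=interval,
            temperature=float(meta.get("temperature_C", 30.0)),
            label=meta.get("label", path.stem),
            processing_log=[f"loaded from {path.name}"],
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_thermogram(tg: Thermogram, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# unit: time=s power=ucal/s\n")
        fh.write(f"# temperature_C: {tg.temperature:g}\n")
        fh.write(f"# label: {tg.label}\n")
        fh.write(f"# sample_interval_s: {tg.sample_interval!r}\n")
        tg.to_frame().to_csv(fh, index=False, float_format=lambda x: repr(float(x)))


def read_injection_schedule(path) -> InjectionSchedule:
    """Read an injection schedule (columns ``time_s``, ``volume_uL``,
    ``syringe_conc_uM``; optional ``# syringe_capacity_uL:`` header)."""
    path = Path(path)
    meta, body = _split_header(path.read_text())
    if not body.strip():
        raise ParseError(f"{path}: no injection events")
    df = _read_table(body, path)
    _require_columns(df, ["time_s", "volume_uL", "syringe_conc_uM"], path)
    if len(df) == 0:
        raise ParseError(f"{path}: no injection events")
    rows = list(
        zip(
            df["time_s"].to_numpy(dtype=float),
            df["volume_uL"].to_numpy(dtype=float),
            df["syringe_conc_uM"].to_numpy(dtype=float),
        )
    )
    capacity = meta.get("syringe_capacity_uL")
    try:
        return InjectionSchedule(
            events=rows,
            syringe_capacity=float(capacity) if capacity is not None else None,
            label=meta.get("label", path.stem),
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_injection_schedule(schedule: InjectionSchedule, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# label: {schedule.label}\n")
        if schedule.syringe_capacity is not None:
            fh.write(f"# syringe_capacity_uL: {schedule.syringe_capacity:g}\n")
        schedule.to_frame().to_csv(fh, index=False)


_RATE_COLUMNS = ["time_s", "S_uM", "rate_uM_per_s", "injection_idx", "retained"]


def write_rate_curve(rc: RateCurve, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for start, end, reason in rc.excluded_windows:
            fh.write(f"# excluded_window: {start:g} {end:g} {reason}\n")
        rc.data[_RATE_COLUMNS + ["reason"]].to_csv(
            fh, index=False, float_format=lambda x: repr(float(x))
        )


def read_rate_curve(path) -> RateCurve:
    path = Path(path)
    meta_lines = [
        ln.lstrip("#").strip()
        for ln in path.read_text().splitlines()
        if ln.strip().startswith("#")
    ]
    windows = []
    for ln in meta_lines:
        if ln.startswith("excluded_window:"):
            start, end, reason = ln.split(":", 1)[1].split()
            windows.append((float(start), float(end), reason))
    _, body = _split_header(path.read_text())
    df = _read_table(body, path)
    _require_columns(df, _RATE_COLUMNS, path)
    df["retained"] = df["retained"].astype(bool)
    if "reason" in df.columns:
        df["reason"] = df["reason"].fillna("")
    return RateCurve(data=df, excluded_windows=windows)


def read_absorbance_trace(path):
    """Read an absorbance trace (columns ``time_s``, ``absorbance_AU``).

    Required headers: ``# substrate_conc_uM:`` plus assay keys
    ``# wavelength_nm:`` and ``# extinction_M_cm:``.
    Returns an :class:`itckinetics.spectro.AbsorbanceTrace`.
    """
    from .spectro import AbsorbanceTrace

    path = Path(path)
    meta, body = _split_header(path.read_text())
    df = _read_table(body, path)
    _require_columns(df, ["time_s", "absorbance_AU"], path)
    for key in ("substrate_conc_uM", "wavelength_nm", "extinction_M_cm"):
        if key not in meta:
            raise ParseError(f"{path}: missing required header '# {key}:'")
    assay = AssayConfig(
        wavelength=float(meta["wavelength_nm"]),
        extinction_coefficient=float(meta["extinction_M_cm"]),
        path_length=float(meta.get("path_length_cm", 1.0)),
        ph=float(meta["pH"]) if "pH" in meta else None,
        temperature=float(meta["temperature_C"]) if "temperature_C" in meta else None,
    )
    return AbsorbanceTrace(
        time=df["time_s"].to_numpy(dtype=float),
        absorbance=df["absorbance_AU"].to_numpy(dtype=float),
        substrate_conc=float(meta["substrate_conc_uM"]),
        assay=assay,
    )


def write_absorbance_trace(trace, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# substrate_conc_uM: {trace.substrate_conc!r}\n")
        fh.write(f"# wavelength_nm: {trace.assay.wavelength:g}\n")
        fh.write(f"# extinction_M_cm: {trace.assay.extinction_coefficient:g}\n")
        fh.write(f"# path_length_cm: {trace.assay.path_length:g}\n")
        if trace.assay.ph is not None:
            fh.write(f"# pH: {trace.assay.ph:g}\n")
        if trace.assay.temperature is not None:
            fh.write(f"# temperature_C: {trace.assay.temperature:g}\n")
        pd.DataFrame(
            {"time_s": trace.time, "absorbance_AU": trace.absorbance}
        ).to_csv(fh, index=False, float_format=lambda x: repr(float(x)))


def load_config(path) -> dict:
    """Load a YAML run configuration.

    Recognised sections: ``cell`` (volume_uL, enzyme_conc_uM, buffer,
    molecular_weight_g_mol), ``assay`` (wavelength_nm, extinction_M_cm,
    path_length_cm, reaction_volume_mL, enzyme_mass_mg, pH, temperature_C),
    ``instrument`` (tau_s), plus free keys (``seed``, paths).  Returns a dict
    with ``cell``/``assay`` replaced by constructed config objects.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: configuration must be a mapping")
    out = dict(raw)
    if "cell" in raw:
        c = raw["cell"]
        out["cell"] = CellConfig(
            volume=c["volume_uL"],
            enzyme_conc=c.get("enzyme_conc_uM", 0.0),
            buffer=c.get("buffer", ""),
            molecular_weight=c.get("molecular_weight_g_mol"),
        )
    if "assay" in raw:
        a = raw["assay"]
        out["assay"] = AssayConfig(
            wavelength=a["wavelength_nm"],
            extinction_coefficient=a["extinction_M_cm"],
            path_length=a.get("path_length_cm", 1.0),
            reaction_volume=a.get("reaction_volume_mL"),
            enzyme_mass=a.get("enzyme_mass_mg"),
            ph=a.get("pH"),
            temperature=a.get("temperature_C"),
        )
    return out
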