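"""Readers and writers for gas-exchange tables, A-Ci curves and PAM logs.

One canonical delimited dialect is used throughout: comma-separated,
``.`` decimal, UTF-8, Unix newlines.  Metadata travels in ``#``-prefixed
``key=value`` header lines, so a file written by the simulator carries
its CO2 setpoint, seed and ground-truth parameters and round-trips
losslessly (to 6 significant digits of the numeric payload).
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, TextIO

import numpy as np
import pandas as pd
import yaml

from .fvcb import ACiCurve
from .trace import FLUOR_COLUMNS, GasExchangeTrace, REQUIRED_COLUMNS

__all__ = [
    "FormatError",
    "read_gas_exchange",
    "write_gas_exchange",
    "read_aci_curve",
    "write_aci_curve",
    "read_pam_log",
    "write_pam_log",
    "RunConfig",
]


class FormatError(ValueError):
    """A file violates the expected table format."""


def _parse_meta_value(raw: str) -> Any:
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def _split_header(path: str | Path) -> tuple[dict[str, Any], str, int]:
    """Return (metadata, csv body, number of header lines)."""
    meta: dict[str, Any] = {}
    body_lines: list[str] = []
    n_header = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, raw = stripped.partition("=")
                    meta[key.strip()] = _parse_meta_value(raw.strip())
            else:
                body_lines.append(line)
    return meta, "".join(body_lines), n_header


def read_gas_exchange(path: str | Path) -> GasExchangeTrace:
    """Read a gas-exchange table (columns ``time_s,ppfd,A,gs,Ci,Ca,Tleaf``
    plus optional ``Fs,Fm_prime``; ``#`` metadata header).

    Invariant violations are reported with 1-based file line numbers.
    """
    meta, body, n_header = _split_header(path)
    if not body.strip():
        raise FormatError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO(body))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if len(bad):
        line = n_header + 1 + int(bad[0]) + 2  # +header row, 1-based, next row
        raise FormatError(f"{path}: time_s not strictly increasing at line {line}")
    if all(c in df.columns for c in FLUOR_COLUMNS) and df[FLUOR_COLUMNS].isna().all(
        axis=None
    ):
        df = df.drop(columns=FLUOR_COLUMNS)
    try:
        return GasExchangeTrace(df, meta)
    except ValueError as err:
        raise FormatError(f"{path}: {err}") from err


def write_gas_exchange(trace: GasExchangeTrace, path: str | Path) -> None:
    """Write a trace in the canonical dialect with metadata header."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, val in trace.metadata.items():
            fh.write(f"# {key}={val}\n")
        trace.data.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_aci_curve(path: str | Path) -> ACiCurve:
    """Read an A-Ci curve: ``Ci,A`` columns, optional ``#`` header
    carrying ``ppfd`` and ``leaf_temp``."""
    meta, body, _ = _split_header(path)
    if not body.strip():
        raise FormatError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO(body))
    for col in ("Ci", "A"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col}")
    try:
        return ACiCurve.from_points(
            list(zip(df["Ci"].astype(float), df["A"].astype(float))),
            ppfd=float(meta.get("ppfd", 1500.0)),
            leaf_temp=float(meta.get("leaf_temp", 30.0)),
        )
    except ValueError as err:
        raise FormatError(f"{path}: {err}") from err


def write_aci_curve(curve: ACiCurve, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# ppfd={curve.ppfd}\n# leaf_temp={curve.leaf_temp}\n")
        fh.write("Ci,A\n")
        for c, a in zip(curve.ci, curve.a):
            fh.write(f"{c:.10g},{a:.10g}\n")


def read_pam_log(path: str | Path) -> pd.DataFrame:
    """Read a field PAM log: ``datetime,ppfd,Fs,Fm_prime`` (or ``time_s``
    already in seconds).  Returns a DataFrame with ``time_s`` relative to
    the first record; an optional ``head`` column is preserved.
    """
    meta, body, _ = _split_header(path)
    if not body.strip():
        raise FormatError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO(body))
    if "time_s" not in df.columns:
        if "datetime" not in df.columns:
            raise FormatError(f"{path}: need a 'datetime' or 'time_s' column")
        dt = pd.to_datetime(df["datetime"])
        df["time_s"] = (dt - dt.iloc[0]).dt.total_seconds()
    for col in ("ppfd", "Fs", "Fm_prime"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: timestamps not strictly increasing")
    df.attrs.update(meta)
    return df


def write_pam_log(df: pd.DataFrame, path: str | Path,
                  metadata: dict[str, Any] | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS: dict[str, dict[str, Any]] = {
    "kinetics": {"Kc": 690.05, "Ko": 353.02, "gamma_star": 55.22,
                 "Rd": 1.37, "O": 210.0},
    "fit": {"theta": 0.7, "alpha": 0.3, "max_iter": 20,
            "steady_window_s": 120.0, "horizon_s": 600.0},
    "leaf": {"Vcmax": 85.0, "Jmax": 125.0, "gs_min": 0.05, "gs_max": 0.45,
             "tau_gs_open": 300.0, "tau_gs_close": 120.0, "tau_act": 240.0,
             "act_dark": 0.3, "gs_target_ppfd_sat": 1000.0,
             "act_ppfd_sat": 400.0},
    "regime": {"low": 50.0, "high": 1500.0, "t_low_s": 1200.0,
               "t_high_s": 1800.0, "interval_s": 10.0,
               "peak_ppfd": 1200.0, "day_length_s": 43200.0,
               "shade_fraction": 0.2, "dwell_lo_s": 10.0,
               "dwell_hi_s": 300.0, "p_sun": 0.5,
               "pam_interval_s": 180.0},
    "noise": {"sd_A": 0.3, "cv_gs": 0.02, "sd_fluor": 5.0},
    "pam": {"phi0": 0.78, "K": 450.0, "fs_baseline": 500.0},
    "run": {"seed": 0, "co2_ppm": 400.0,
            "ppfd_bin_edges": [0, 200, 400, 600, 800, 1000, 1200, 1500]},
}


@dataclass
class RunConfig:
    """Nested run configuration with strict key checking.

    Sections: ``kinetics`` (FvCB constants), ``fit`` (fit options),
    ``leaf`` (simulator leaf), ``regime`` (light schedules), ``noise``,
    ``pam`` (field fluorescence model) and ``run`` (seed, CO2, binning).
    Unknown sections or keys are rejected; the fully resolved document is
    serialised into every output's metadata for provenance.
    """

    sections: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        resolved = {k: dict(v) for k, v in _CONFIG_SECTIONS.items()}
        for sec, vals in (self.sections or {}).items():
            if sec not in resolved:
                raise ValueError(f"unknown config section {sec!r}")
            if not isinstance(vals, dict):
                raise ValueError(f"config section {sec!r} must be a mapping")
            for key, val in vals.items():
                if key not in resolved[sec]:
                    raise ValueError(f"unknown config key {sec}.{key}")
                resolved[sec][key] = val
        self.sections = resolved

    def __getitem__(self, section: str) -> dict[str, Any]:
        return self.sections[section]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls(doc)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.sections, sort_keys=True)

    def flat(self) -> dict[str, Any]:
        return {
            f"{sec}.{key}": val
            for sec, vals in self.sections.items()
            for key, val in vals.items()
        }
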