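"""Chlorophyll-fluorescence analysis: PSII efficiency, ETR and NPQ.

Pulse-amplitude-modulated (PAM) fluorometry yields the steady-state
fluorescence ``Fs`` and the maximal fluorescence during a saturating
pulse ``Fm'`` on an illuminated leaf.  The PSII operating efficiency is
``PhiPSII = (Fm' - Fs)/Fm'`` and the linear electron transport rate is

    ETR = 0.5 * 0.84 * PhiPSII * PPFD

where 0.5 is the fraction of absorbed photons reaching PSII and 0.84 the
leaf absorptance.  Nonphotochemical quenching relative to the
dark-adapted maximal fluorescence ``Fm`` is ``NPQ = (Fm - Fm')/Fm'``.

Traces sampled across a day are integrated by the trapezoidal rule over
the actual timestamps to give mol electrons m-2 per trace duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceRecord",
    "EtrTrace",
    "phi_psii",
    "etr",
    "npq",
    "etr_trace",
    "etr_vs_ppfd",
]

PSII_FRACTION = 0.5
LEAF_ABSORPTANCE = 0.84


@dataclass(frozen=True)
class FluorescenceRecord:
    """One PAM measurement: time (s from trace start), PPFD, Fs, Fm'."""

    time: float
    ppfd: float
    Fs: float
    Fm_prime: float

    def __post_init__(self) -> None:
        if self.Fs <= 0 or self.Fm_prime <= 0:
            raise ValueError("Fs and Fm_prime must be strictly positive")
        if self.ppfd < 0:
            raise ValueError("ppfd must be non-negative")


@dataclass(frozen=True)
class EtrTrace:
    """Per-record PhiPSII/ETR plus the trace-level integrated ETR.

    ``integrated_etr`` is in mol electrons m-2 over the trace duration;
    ``flagged`` marks records where Fs exceeded Fm' (instrument noise)
    and PhiPSII was clamped to zero.
    """

    time: np.ndarray
    ppfd: np.ndarray
    phi_psii: np.ndarray
    etr: np.ndarray
    integrated_etr: float
    sampling_interval: float
    flagged: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "ppfd": self.ppfd,
                "phi_psii": self.phi_psii,
                "etr": self.etr,
                "flagged": self.flagged,
            }
        )


def phi_psii(Fs, Fm_prime, clamp: bool = True):
    """PSII operating efficiency (Fm' - Fs)/Fm', dimensionless in [0, 1].

    Records with Fs > Fm' (bad saturating pulses) are clamped to 0 with a
    warning when ``clamp`` is true.
    """
    Fs = np.asarray(Fs, dtype=float)
    Fm_prime = np.asarray(Fm_prime, dtype=float)
    if np.any(Fm_prime <= 0):
        raise ValueError("Fm_prime must be strictly positive")
    phi = (Fm_prime - Fs) / Fm_prime
    bad = phi < 0
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} record(s) with Fs > Fm_prime; "
            "PhiPSII clamped to 0",
            stacklevel=2,
        )
        if clamp:
            phi = np.where(bad, 0.0, phi)
    return phi if phi.ndim else float(phi)


def etr(
    Fs,
    Fm_prime,
    ppfd,
    psii_fraction: float = PSII_FRACTION,
    absorptance: float = LEAF_ABSORPTANCE,
):
    """Linear electron transport rate, umol e- m-2 s-1.

    ETR = psii_fraction * absorptance * PhiPSII * PPFD, bounded above by
    psii_fraction * absorptance * PPFD (0.42*PPFD at the defaults).
    """
    ppfd = np.asarray(ppfd, dtype=float)
    if np.any(ppfd < 0):
        raise ValueError("ppfd must be non-negative")
    out = psii_fraction * absorptance * phi_psii(Fs, Fm_prime) * ppfd
    return out if out.ndim else float(out)


def npq(Fm, Fm_prime):
    """Nonphotochemical quenching (Fm - Fm')/Fm'.

    ``Fm`` is the dark-adapted maximal fluorescence.  Negative values
    (Fm' exceeding Fm, e.g. a drifting baseline) are reported as-is with
    a warning rather than clamped.
    """
    Fm = np.asarray(Fm, dtype=float)
    Fm_prime = np.asarray(Fm_prime, dtype=float)
    if np.any(Fm <= 0) or np.any(Fm_prime <= 0):
        raise ValueError("Fm and Fm_prime must be strictly positive")
    out = (Fm - Fm_prime) / Fm_prime
    if np.any(out < 0):
        warnings.warn(
            f"{int(np.sum(out < 0))} record(s) with Fm < Fm_prime; "
            "negative NPQ reported unclamped",
            stacklevel=2,
        )
    return out if out.ndim else float(out)


def etr_trace(
    records: Sequence[FluorescenceRecord] | pd.DataFrame,
    psii_fraction: float = PSII_FRACTION,
    absorptance: float = LEAF_ABSORPTANCE,
) -> EtrTrace:
    """Compute per-record PhiPSII/ETR and the trapezoid-integrated ETR.

    Accepts a list of :class:`FluorescenceRecord` or a DataFrame with
    columns ``time_s, ppfd, Fs, Fm_prime``.  Integration uses the actual
    timestamps, so gaps are handled; gaps larger than 3x the nominal
    (median) interval trigger a warning.
    """
    if isinstance(records, pd.DataFrame):
        t = records["time_s"].to_numpy(dtype=float)
        ppfd = records["ppfd"].to_numpy(dtype=float)
        fs = records["Fs"].to_numpy(dtype=float)
        fmp = records["Fm_prime"].to_numpy(dtype=float)
    else:
        t = np.array([r.time for r in records], dtype=float)
        ppfd = np.array([r.ppfd for r in records], dtype=float)
        fs = np.array([r.Fs for r in records], dtype=float)
        fmp = np.array([r.Fm_prime for r in records], dtype=float)
    if len(t) < 2:
        raise ValueError("etr_trace needs at least 2 records")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise ValueError(f"timestamps not strictly increasing at index {bad + 1}")
    nominal = float(np.median(dt))
    if np.any(dt > 3.0 * nominal):
        warnings.warn(
            "sampling gap(s) exceeding 3x the nominal interval; "
            "trapezoid integration still applied",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        phi = np.atleast_1d(phi_psii(fs, fmp))
    flagged = (fmp - fs) < 0
    e = psii_fraction * absorptance * phi * ppfd
    integrated = float(np.trapezoid(e, t)) * 1e-6  # umol -> mol
    return EtrTrace(
        time=t,
        ppfd=ppfd,
        phi_psii=phi,
        etr=e,
        integrated_etr=integrated,
        sampling_interval=nominal,
        flagged=flagged,
    )


def etr_vs_ppfd(trace: EtrTrace, bin_edges: Sequence[float]) -> pd.DataFrame:
    """Bin ETR by PPFD; per-bin mean, SE and n.

    Bins are left-open/right-closed ``(lo, hi]``.  Empty bins are omitted
    from the rows and listed in the frame's ``attrs['empty_bins']``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with >= 2 edges")
    if len(trace.etr) == 0:
        raise ValueError("empty trace")
    cats = pd.cut(trace.ppfd, bins=edges, right=True, include_lowest=False)
    df = pd.DataFrame({"bin": cats, "etr": trace.etr})
    grouped = df.groupby("bin", observed=False)["etr"]
    out = grouped.agg(n="count", mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
    out = out.reset_index()
    empty = [str(b) for b in out.loc[out["n"] == 0, "bin"]]
    out = out[out["n"] > 0].reset_index(drop=True)
    out.attrs["empty_bins"] = empty
    return out
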