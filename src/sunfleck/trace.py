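"""Gas-exchange trace container shared by every analysis stage.

A :class:`GasExchangeTrace` wraps a time-ordered table of synchronized
gas-exchange records (PPFD, A, gs, Ci, Ca, leaf temperature) with
optional chamber-fluorescence columns (Fs, Fm') and free-form metadata
(CO2 setpoint, cultivar/treatment labels, simulator ground truth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["GasExchangeTrace", "REQUIRED_COLUMNS", "FLUOR_COLUMNS"]

REQUIRED_COLUMNS = ["time_s", "ppfd", "A", "gs", "Ci", "Ca", "Tleaf"]
FLUOR_COLUMNS = ["Fs", "Fm_prime"]


@dataclass
class GasExchangeTrace:
    """Time series of gas-exchange (+ optional fluorescence) records.

    ``data`` columns: time_s (s), ppfd (umol photons m-2 s-1),
    A (umol CO2 m-2 s-1), gs (mol H2O m-2 s-1), Ci and Ca (umol mol-1),
    Tleaf (degC), and optionally Fs / Fm_prime (instrument units).
    """

    data: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        self.data = self.data.reset_index(drop=True)
        t = self.data["time_s"].to_numpy(dtype=float)
        if len(t) == 0:
            raise ValueError("empty trace")
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"time not strictly increasing at row {bad}")
        for col, cond in (("gs", self.data["gs"] <= 0), ("Ca", self.data["Ca"] <= 0),
                          ("Ci", self.data["Ci"] <= 0)):
            if cond.any():
                bad = int(np.argmax(cond.to_numpy()))
                raise ValueError(f"non-positive {col} at row {bad}")
        over = self.data["Ci"] > self.data["Ca"]
        if over.any():
            # transient Ci > Ca (respiration in darkness) is legal but flagged
            warnings.warn(
                f"{int(over.sum())} record(s) with Ci > Ca "
                "(expected only in darkness)",
                stacklevel=2,
            )

    # -- convenience accessors -------------------------------------------
    @property
    def time(self) -> np.ndarray:
        return self.data["time_s"].to_numpy(dtype=float)

    @property
    def duration(self) -> float:
        t = self.time
        return float(t[-1] - t[0])

    @property
    def has_fluorescence(self) -> bool:
        return all(c in self.data.columns for c in FLUOR_COLUMNS) and bool(
            self.data[FLUOR_COLUMNS].notna().all(axis=None)
        )

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def window(self, t0: float, t1: float) -> "GasExchangeTrace":
        """Sub-trace with t0 <= time_s <= t1 (metadata carried over)."""
        mask = (self.data["time_s"] >= t0) & (self.data["time_s"] <= t1)
        if not mask.any():
            raise ValueError(f"no records in window [{t0}, {t1}]")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return GasExchangeTrace(self.data[mask].copy(), dict(self.metadata))
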