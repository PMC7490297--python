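"""Daily-scale analysis of gas exchange under fluctuating light.

Integrates net assimilation over a day (total daily carbon gain),
summarises stomatal conductance, Ci/Ca and intrinsic water-use
efficiency as duration-weighted means, bins A and gs by PPFD, and
provides the group mean +/- SE and percent-difference arithmetic used to
compare cultivar x nitrogen x CO2 treatment groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .fluorescence import etr_trace
from .trace import GasExchangeTrace

__all__ = [
    "DailySummary",
    "GroupSummary",
    "integrate_assimilation",
    "bin_by_ppfd",
    "percent_difference",
    "co2_doubling_increase",
    "group_summary",
    "daily_summary",
    "summary_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SE of one variable in one treatment group (n leaves)."""

    label: str
    n: int
    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.se < 0:
            raise ValueError("se must be non-negative")

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.se:.2f}"


@dataclass(frozen=True)
class DailySummary:
    """Whole-trace aggregates for one leaf-day."""

    integrated_A: float  # mol CO2 m-2 over the trace duration
    mean_gs: float
    mean_Ci_over_Ca: float
    mean_iwue: float
    duration: float  # s
    integrated_etr: float | None = None  # mol e- m-2, if fluorescence present
    ci_ca_in_range: bool = True
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "integrated_A_mol_m2": self.integrated_A,
            "mean_gs": self.mean_gs,
            "mean_Ci_over_Ca": self.mean_Ci_over_Ca,
            "mean_iwue": self.mean_iwue,
            "duration_s": self.duration,
            "integrated_etr_mol_m2": self.integrated_etr,
            "ci_ca_in_range": self.ci_ca_in_range,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def integrate_assimilation(trace: GasExchangeTrace, method: str = "trapezoid") -> float:
    """Total carbon gain: time integral of A over the trace, mol CO2 m-2.

    Trapezoidal by default over the actual timestamps; ``rectangle``
    (left-Riemann) is available since the two agree to < 0.1% at 10-s
    sampling of smooth traces.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    if trace.duration < 3600.0:
        raise ValueError("daily integration expects a trace of at least 1 h")
    t = trace.time
    a = trace.column("A")
    if method == "trapezoid":
        total = float(np.trapezoid(a, t))
    elif method == "rectangle":
        total = float(np.sum(a[:-1] * np.diff(t)))
    else:
        raise ValueError("method must be 'trapezoid' or 'rectangle'")
    return total * 1e-6  # umol -> mol


def bin_by_ppfd(trace: GasExchangeTrace, edges: Sequence[float]) -> pd.DataFrame:
    """Per-PPFD-bin mean, SE and n of A and gs.

    Bins are left-open/right-closed ``(lo, hi]``; empty bins are omitted
    and listed in ``attrs['empty_bins']``.
    """
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be increasing with >= 2 edges")
    if len(trace) == 0:
        raise ValueError("empty trace")
    cats = pd.cut(trace.column("ppfd"), bins=edges, right=True)
    df = pd.DataFrame({"bin": cats, "A": trace.column("A"), "gs": trace.column("gs")})

    def _se(v):
        return v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0

    grouped = df.groupby("bin", observed=False)
    out = grouped.agg(
        n=("A", "count"),
        A_mean=("A", "mean"),
        A_se=("A", _se),
        gs_mean=("gs", "mean"),
        gs_se=("gs", _se),
    ).reset_index()
    empty = [str(b) for b in out.loc[out["n"] == 0, "bin"]]
    out = out[out["n"] > 0].reset_index(drop=True)
    out.attrs["empty_bins"] = empty
    return out


def percent_difference(reference: float, other: float) -> float:
    """Percent difference of ``other`` relative to ``reference``:
    100*(other - reference)/reference."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (other - reference) / reference


def co2_doubling_increase(a400: GroupSummary, a800: GroupSummary) -> float:
    """Percent increase of steady-state A from 400 to 800 ppm CO2.

    The two summaries must describe the same cultivar x N group, with
    labels of the form ``<group>@400`` / ``<group>@800`` or identical.
    """
    g400 = a400.label.split("@")[0]
    g800 = a800.label.split("@")[0]
    if g400 != g800:
        raise ValueError(
            f"group labels do not match: {a400.label!r} vs {a800.label!r}"
        )
    return percent_difference(a400.mean, a800.mean)


def group_summary(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean +/- SE (sample sd / sqrt(n)) of replicate leaves."""
    v = np.asarray(list(values), dtype=float)
    if len(v) == 0:
        raise ValueError("empty group")
    se = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
    return GroupSummary(label=label, n=len(v), mean=float(np.mean(v)), se=se)


def _time_weighted_mean(t: np.ndarray, v: np.ndarray) -> float:
    if len(t) == 1:
        return float(v[0])
    return float(np.trapezoid(v, t) / (t[-1] - t[0]))


def daily_summary(trace: GasExchangeTrace) -> DailySummary:
    """Aggregate one leaf-day: integrated A, duration-weighted means of
    gs, Ci/Ca and iWUE, and integrated ETR when fluorescence is present.

    Ci/Ca and iWUE are computed per record and then averaged (not ratios
    of averages).  A mean Ci/Ca outside (0.3, 1.0) is flagged.
    """
    t = trace.time
    integrated = integrate_assimilation(trace)
    gs = trace.column("gs")
    ci_ca = trace.column("Ci") / trace.column("Ca")
    wue = trace.column("A") / gs
    mean_ci_ca = _time_weighted_mean(t, ci_ca)
    integrated_etr = None
    if trace.has_fluorescence:
        sub = trace.data[["time_s", "ppfd", "Fs", "Fm_prime"]].dropna()
        integrated_etr = etr_trace(sub).integrated_etr
    return DailySummary(
        integrated_A=integrated,
        mean_gs=_time_weighted_mean(t, gs),
        mean_Ci_over_Ca=mean_ci_ca,
        mean_iwue=_time_weighted_mean(t, wue),
        duration=trace.duration,
        integrated_etr=integrated_etr,
        ci_ca_in_range=bool(0.3 < mean_ci_ca < 1.0),
        metadata=dict(trace.metadata),
    )


def summary_table(groups: dict[str, dict[str, GroupSummary]]) -> pd.DataFrame:
    """Assemble a parameter x group table of ``mean +/- se`` cells.

    ``groups`` maps group label -> {parameter name -> GroupSummary};
    rows are parameters, columns are groups (cultivar x treatment).
    """
    params: list[str] = []
    for d in groups.values():
        for p in d:
            if p not in params:
                params.append(p)
    table = {
        label: {p: (str(d[p]) if p in d else "") for p in params}
        for label, d in groups.items()
    }
    return pd.DataFrame(table, index=params)
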