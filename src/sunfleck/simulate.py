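"""Dynamic-leaf simulator and synthetic light regimes.

Stands in for the gas-exchange instrument: every analysis stage in this
package can be exercised against traces whose ground truth is known.

The forward model couples three components at each time step:

1.  **Stomata** — gs relaxes first-order toward a PPFD-dependent target
    (linear between ``gs_min`` and ``gs_max`` up to a saturating PPFD),
    with separate opening and closing time constants (opening is slower
    in real leaves).
2.  **Biochemistry** — a scalar activation state (Rubisco/Calvin-cycle
    activation) multiplies Vcmax; it relaxes toward 1 under light and
    toward a dark-resting value in darkness, with time constant
    ``tau_act``.  Electron transport J responds to PPFD instantaneously.
3.  **CO2 diffusion** — at each step the intercellular CO2 mole fraction
    Ci solves the supply-demand balance
    ``A_demand(Ci) = (gs/1.6) * (Ca - Ci)`` by bisection; the matched A
    is the simulated assimilation rate.

Chamber fluorescence is synthesised so that Eq.-style ETR recomputed
from (Fs, Fm', PPFD) equals ``4*(A + Rd)`` capped at J(PPFD), keeping
gas exchange and fluorescence mutually consistent for round-trip tests.

Light regimes: a two-level step protocol (sunfleck induction
experiments), a 12-h diurnal half-sine envelope modulated by a two-state
sun/shade telegraph process with log-uniform dwell times (fluctuating
canopy light), and 3-min-sampled field PAM schedules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from .fluorescence import FluorescenceRecord, LEAF_ABSORPTANCE, PSII_FRACTION
from .fvcb import (
    ACiCurve,
    FvCBParams,
    LeafKinetics,
    j_light_response,
    rubisco_limited_rate,
    rubp_limited_rate,
)
from .trace import GasExchangeTrace

__all__ = [
    "LightRegime",
    "SimLeaf",
    "NoiseModel",
    "CiSolverError",
    "step_light_protocol",
    "generate_diurnal_regime",
    "solve_ci",
    "simulate_leaf",
    "generate_aci_curve",
    "generate_pam_trace",
]


class CiSolverError(RuntimeError):
    """Raised when the supply-demand bracket has no sign change."""


@dataclass(frozen=True)
class LightRegime:
    """A PPFD schedule: strictly increasing times at a fixed interval."""

    time: np.ndarray  # s
    ppfd: np.ndarray  # umol photons m-2 s-1
    kind: str = "step"  # step | diurnal-fluctuating | field-PAM
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.ppfd, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "ppfd", p)
        if len(t) != len(p):
            raise ValueError("time and ppfd must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("ppfd must be non-negative")

    @property
    def interval(self) -> float:
        return float(np.median(np.diff(self.time)))

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class SimLeaf:
    """Ground-truth parameters of the simulated leaf.

    ``gs_target_ppfd_sat`` is the PPFD at which the steady-state gs
    target reaches ``gs_max``; below it the target is linear in PPFD.
    ``act_dark`` is the dark-resting Rubisco activation state and
    ``act_ppfd_sat`` the PPFD at which the steady activation target
    reaches 1 (linear in between).  The default sits at the dim
    background level of step protocols, so any working light keeps the
    target fully activated and the induction transient is stomatal;
    raise it to give the activation state its own induction lag.  ``gb`` is the boundary-layer
    conductance; the default (infinite: chamber-fan regime) makes the
    CO2 supply conductance exactly gs/1.6.
    """

    fvcb: FvCBParams
    kin: LeafKinetics = field(default_factory=LeafKinetics)
    gs_min: float = 0.05
    gs_max: float = 0.45
    tau_gs_open: float = 300.0
    tau_gs_close: float = 120.0
    tau_act: float = 240.0
    act_dark: float = 0.3
    gs_target_ppfd_sat: float = 1000.0
    act_ppfd_sat: float = 50.0
    gb: float = math.inf

    def __post_init__(self) -> None:
        if not (0 < self.gs_min < self.gs_max):
            raise ValueError("need 0 < gs_min < gs_max")
        for name in ("tau_gs_open", "tau_gs_close", "tau_act"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.act_dark <= 1):
            raise ValueError("act_dark must lie in (0, 1]")

    def gs_target(self, ppfd: float) -> float:
        """Steady-state stomatal conductance at a given PPFD."""
        frac = min(max(ppfd, 0.0) / self.gs_target_ppfd_sat, 1.0)
        return self.gs_min + (self.gs_max - self.gs_min) * frac

    def act_target(self, ppfd: float) -> float:
        """Steady Rubisco activation state at a given PPFD (1 at
        saturating light, ``act_dark`` in darkness, linear between)."""
        frac = min(max(ppfd, 0.0) / self.act_ppfd_sat, 1.0)
        return self.act_dark + (1.0 - self.act_dark) * frac

    def to_metadata(self) -> dict[str, float]:
        return {
            "truth_Vcmax": self.fvcb.Vcmax,
            "truth_Jmax": self.fvcb.Jmax,
            "truth_theta": self.fvcb.theta,
            "truth_alpha": self.fvcb.alpha,
            "truth_gs_min": self.gs_min,
            "truth_gs_max": self.gs_max,
            "truth_tau_gs_open": self.tau_gs_open,
            "truth_tau_gs_close": self.tau_gs_close,
            "truth_tau_act": self.tau_act,
        }


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: additive on A and fluorescence, multiplicative
    (fractional) on gs.  ``NoiseModel.none()`` disables all noise."""

    sd_A: float = 0.3
    cv_gs: float = 0.02
    sd_fluor: float = 5.0

    def __post_init__(self) -> None:
        if self.sd_A < 0 or self.cv_gs < 0 or self.sd_fluor < 0:
            raise ValueError("noise magnitudes must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(sd_A=0.0, cv_gs=0.0, sd_fluor=0.0)


# ---------------------------------------------------------------------------
# light regimes
# ---------------------------------------------------------------------------

def step_light_protocol(
    low: float = 50.0,
    high: float = 1500.0,
    t_low: float = 1200.0,
    t_high: float = 1800.0,
    interval: float = 10.0,
) -> LightRegime:
    """Two-level step: low-light adaptation then a sudden increase.

    Defaults follow the chamber protocol: 20 min at 50 then 30 min at
    1500 umol photons m-2 s-1, sampled every 10 s.
    """
    if low >= high:
        raise ValueError("low must be below high")
    if t_high <= 0 or t_low < 0:
        raise ValueError("durations must be positive (t_low may be 0)")
    n_low = int(round(t_low / interval))
    n_high = int(round(t_high / interval))
    t = np.arange(n_low + n_high) * interval
    p = np.concatenate([np.full(n_low, low), np.full(n_high, high)])
    return LightRegime(time=t, ppfd=p, kind="step")


def generate_diurnal_regime(
    peak_ppfd: float = 1200.0,
    day_length: float = 12 * 3600.0,
    interval: float = 10.0,
    shade_fraction: float = 0.2,
    dwell_bounds: tuple[float, float] = (10.0, 300.0),
    p_sun: float = 0.5,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> LightRegime:
    """Fluctuating canopy light for one day.

    A half-sine envelope (zero at dawn and dusk, ``peak_ppfd`` at noon)
    is multiplied by a two-state sun/shade telegraph process: dwell times
    are log-uniform within ``dwell_bounds`` and the shade state scales
    the envelope by ``shade_fraction``.  ``p_sun`` sets the stationary
    sun probability by scaling the mean shade dwell.  Deterministic for
    a given seed.
    """
    lo, hi = dwell_bounds
    if not (0 < lo < hi):
        raise ValueError("dwell bounds must satisfy 0 < lo < hi")
    if not (0 <= shade_fraction <= 1):
        raise ValueError("shade_fraction must lie in [0, 1]")
    if not (0 < p_sun < 1):
        raise ValueError("p_sun must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    t = np.arange(0.0, day_length + interval / 2, interval)
    envelope = peak_ppfd * np.sin(np.pi * t / day_length)
    envelope = np.clip(envelope, 0.0, None)

    if shade_fraction == 1.0:
        factor = np.ones_like(t)
    else:
        # alternating sun/shade dwells; shade dwells scaled so the
        # stationary sun fraction E[d_sun]/(E[d_sun]+E[d_shade]) = p_sun
        scale_shade = (1.0 - p_sun) / p_sun
        state_sun = bool(rng.integers(0, 2))
        switch_ends: list[float] = []
        states: list[bool] = []
        pos = 0.0
        while pos <= day_length:
            dwell = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            if not state_sun:
                dwell *= scale_shade
            pos += dwell
            switch_ends.append(pos)
            states.append(state_sun)
            state_sun = not state_sun
        idx = np.searchsorted(np.asarray(switch_ends), t, side="right")
        idx = np.clip(idx, 0, len(states) - 1)
        sun = np.asarray(states, dtype=bool)[idx]
        factor = np.where(sun, 1.0, shade_fraction)
    ppfd = envelope * factor
    return LightRegime(time=t, ppfd=ppfd, kind="diurnal-fluctuating",
                       seed=seed)


# ---------------------------------------------------------------------------
# supply-demand Ci solver
# ---------------------------------------------------------------------------

def _demand(ci: float, vcmax_eff: float, j: float, leaf: SimLeaf) -> float:
    kin = leaf.kin
    ac = vcmax_eff * (ci - kin.gamma_star) / (ci + kin.Km) - kin.Rd
    aj = j * (ci - kin.gamma_star) / (4.0 * ci + 8.0 * kin.gamma_star) - kin.Rd
    return min(ac, aj)


def solve_ci(
    gs: float,
    Ca: float,
    ppfd: float,
    leaf: SimLeaf,
    activation: float = 1.0,
    tol: float = 0.005,
) -> tuple[float, float]:
    """Intersect FvCB demand with the diffusion supply line.

    Finds the unique Ci in (0, Ca + margin) where
    ``A_demand(Ci; activation*Vcmax, J(ppfd)) = g_c * (Ca - Ci)`` with
    ``g_c`` the series CO2 conductance of stomata (gs/1.6) and boundary
    layer (gb/1.37), by bisection to |dCi| < ``tol``.  Returns
    ``(Ci, A)``.  In darkness J = 0 forces A = -Rd and Ci above Ca.
    """
    if gs <= 0 or Ca <= 0:
        raise ValueError("gs and Ca must be strictly positive")
    if not (0.0 <= activation <= 1.0):
        raise ValueError("activation must lie in [0, 1]")
    vcmax_eff = activation * leaf.fvcb.Vcmax
    j = j_light_response(ppfd, leaf.fvcb)
    gsc = gs / 1.6
    if math.isfinite(leaf.gb):
        gbc = leaf.gb / 1.37
        gc = gsc * gbc / (gsc + gbc)  # stomata + boundary layer in series
    else:
        gc = gsc

    def f(ci: float) -> float:
        return _demand(ci, vcmax_eff, j, leaf) - gc * (Ca - ci)

    lo = 1e-6
    hi = Ca + 1.6 * (leaf.kin.Rd + 5.0) / gs
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo, _demand(lo, vcmax_eff, j, leaf)
    if fhi == 0.0:
        return hi, _demand(hi, vcmax_eff, j, leaf)
    if flo * fhi > 0:
        raise CiSolverError(
            f"no sign change in [{lo:.3g}, {hi:.3g}]: "
            f"f(lo)={flo:.3g}, f(hi)={fhi:.3g} "
            f"(gs={gs}, Ca={Ca}, ppfd={ppfd}, activation={activation})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0:
            lo = hi = mid
            break
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    ci = 0.5 * (lo + hi)
    return ci, _demand(ci, vcmax_eff, j, leaf)


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def _synth_fluorescence(
    a: float, j: float, ppfd: float, kin: LeafKinetics, fs_baseline: float
) -> tuple[float, float]:
    """Fs, Fm' such that recomputed ETR equals 4*(A + Rd) capped at J."""
    if ppfd <= 0:
        phi = 0.8  # dark-adapted operating efficiency
    else:
        etr_true = min(4.0 * (a + kin.Rd), j)
        phi = max(etr_true, 0.0) / (PSII_FRACTION * LEAF_ABSORPTANCE * ppfd)
        phi = min(phi, 0.95)
    fm_prime = fs_baseline / (1.0 - phi)
    return fs_baseline, fm_prime


def simulate_leaf(
    regime: LightRegime,
    leaf: SimLeaf,
    co2: float = 400.0,
    noise: NoiseModel | None = None,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    leaf_temp: float = 28.0,
    fs_baseline: float = 500.0,
    with_fluorescence: bool = True,
    metadata: dict[str, Any] | None = None,
) -> GasExchangeTrace:
    """Step the dynamic leaf through a light regime.

    At each regime interval gs and the activation state relax first-order
    toward their targets, Ci and A come from :func:`solve_ci`, and
    fluorescence columns are synthesised consistently with A.  Noise, if
    any, is applied last; ground truth is embedded in the metadata.
    """
    noise = noise or NoiseModel.none()
    if rng is None:
        rng = np.random.default_rng(seed)
    t = regime.time
    ppfd = regime.ppfd
    n = len(t)

    # leaf starts adapted to the regime's first light level
    gs = leaf.gs_target(ppfd[0])
    act = leaf.act_target(ppfd[0])

    gs_arr = np.empty(n)
    act_arr = np.empty(n)
    a_arr = np.empty(n)
    ci_arr = np.empty(n)
    fs_arr = np.empty(n)
    fmp_arr = np.empty(n)

    for i in range(n):
        if i > 0:
            dt = t[i] - t[i - 1]
            target = leaf.gs_target(ppfd[i])
            tau = leaf.tau_gs_open if target > gs else leaf.tau_gs_close
            gs += (target - gs) * (1.0 - math.exp(-dt / tau))
            act += (leaf.act_target(ppfd[i]) - act) * (
                1.0 - math.exp(-dt / leaf.tau_act)
            )
        try:
            ci, a = solve_ci(gs, co2, ppfd[i], leaf, activation=act)
        except CiSolverError as err:
            raise CiSolverError(f"step {i} (t={t[i]} s): {err}") from err
        gs_arr[i] = gs
        act_arr[i] = act
        ci_arr[i] = ci
        a_arr[i] = a
        if with_fluorescence:
            j = j_light_response(ppfd[i], leaf.fvcb)
            fs_arr[i], fmp_arr[i] = _synth_fluorescence(
                a, j, ppfd[i], leaf.kin, fs_baseline
            )

    if noise.sd_A > 0:
        a_arr = a_arr + rng.normal(0.0, noise.sd_A, n)
    if noise.cv_gs > 0:
        gs_arr = gs_arr * (1.0 + rng.normal(0.0, noise.cv_gs, n))
        gs_arr = np.clip(gs_arr, 1e-4, None)
    if with_fluorescence and noise.sd_fluor > 0:
        fs_arr = np.clip(fs_arr + rng.normal(0.0, noise.sd_fluor, n), 1.0, None)
        fmp_arr = np.clip(fmp_arr + rng.normal(0.0, noise.sd_fluor, n), 1.0, None)

    cols = {
        "time_s": t,
        "ppfd": ppfd,
        "A": a_arr,
        "gs": gs_arr,
        "Ci": ci_arr,
        "Ca": np.full(n, float(co2)),
        "Tleaf": np.full(n, float(leaf_temp)),
    }
    if with_fluorescence:
        cols["Fs"] = fs_arr
        cols["Fm_prime"] = fmp_arr
    meta: dict[str, Any] = {
        "co2_setpoint_ppm": float(co2),
        "seed": seed,
        "regime_kind": regime.kind,
        **leaf.to_metadata(),
    }
    if metadata:
        meta.update(metadata)
    import warnings as _w

    with _w.catch_warnings():
        # Ci > Ca occurs legitimately in simulated darkness
        _w.simplefilter("ignore")
        return GasExchangeTrace(pd.DataFrame(cols), meta)


def generate_aci_curve(
    leaf: SimLeaf,
    Ca_sequence: Sequence[float] = (
        50, 100, 150, 200, 300, 400, 500, 650, 800, 1000, 1200, 1500,
    ),
    ppfd: float = 1500.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> ACiCurve:
    """Steady-state A-Ci curve of a fully induced leaf.

    For each ambient CO2 the leaf is held at its steady stomatal
    conductance and full activation; (Ci, A) come from the supply-demand
    solver.  Gaussian noise of sd ``noise_sd`` (umol m-2 s-1) may be
    added to A.  Ground truth is carried in the curve via the leaf.
    """
    ca_seq = [float(c) for c in Ca_sequence]
    if any(c <= 0 for c in ca_seq):
        raise ValueError("Ca values must be strictly positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    gs = leaf.gs_target(ppfd)
    pts = []
    for ca in ca_seq:
        ci, a = solve_ci(gs, ca, ppfd, leaf, activation=1.0, tol=1e-4)
        if noise_sd > 0:
            a += rng.normal(0.0, noise_sd)
        pts.append((ci, a))
    return ACiCurve.from_points(pts, ppfd=ppfd)


def generate_pam_trace(
    regime: LightRegime,
    phi0: float = 0.78,
    K: float = 450.0,
    fs_baseline: float = 500.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Synthetic field PAM log at the regime's (3-min) sampling.

    PSII operating efficiency declines hyperbolically with light,
    ``PhiPSII = phi0 / (1 + PPFD/K)``; Fs is a fixed baseline and
    Fm' = Fs / (1 - PhiPSII).  Returns a DataFrame with columns
    ``time_s, ppfd, Fs, Fm_prime``.
    """
    if not (0.0 < phi0 < 1.0):
        raise ValueError("phi0 must lie in (0, 1)")
    if K <= 0:
        raise ValueError("K must be strictly positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    phi = phi0 / (1.0 + regime.ppfd / K)
    fs = np.full(len(regime), float(fs_baseline))
    fmp = fs / (1.0 - phi)
    if noise_sd > 0:
        fs = np.clip(fs + rng.normal(0.0, noise_sd, len(regime)), 1.0, None)
        fmp = np.clip(fmp + rng.normal(0.0, noise_sd, len(regime)), 1.0, None)
        fmp = np.maximum(fmp, fs + 1e-9)
    return pd.DataFrame(
        {"time_s": regime.time, "ppfd": regime.ppfd, "Fs": fs, "Fm_prime": fmp}
    )
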