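"""Photosynthetic induction analysis for step-increase light experiments.

After a sudden increase in irradiance (a sunfleck), net assimilation A
and stomatal conductance gs rise over minutes, limited by stomatal
opening and by Calvin-cycle enzyme activation.  This module fits logistic
induction curves to A(t) and gs(t), integrates cumulative CO2 fixation
over a horizon (CCF_T, 10 min by default), derives induction half-times,
partitions the transient shortfall of A into diffusional (stomatal) and
biochemical components, and computes intrinsic water-use efficiency.

Limitation partitioning follows the Ci-correction approach: the observed
A(t) is rescaled to what it would have been at the final steady-state Ci,
assuming Rubisco-limited kinetics,

    A*(t) = A(t) * [(Ci_f - G*)/(Ci_f + Km)] / [(Ci(t) - G*)/(Ci(t) + Km)]

so the diffusional limitation DL(t) = (A* - A)/A_f is the share of the
steady-state rate lost to low Ci, and the biochemical limitation
BL(t) = (A_f - A*)/A_f is the remainder; BL + DL = 1 - A/A_f identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize

from .fvcb import LeafKinetics
from .trace import GasExchangeTrace

__all__ = [
    "SigmoidFit",
    "LimitationCourse",
    "InductionResult",
    "DegenerateFitError",
    "fit_induction_sigmoid",
    "cumulative_fixation",
    "induction_time",
    "limitation_partition",
    "iwue",
    "analyze_induction",
]


class DegenerateFitError(ValueError):
    """Raised when an induction metric is requested from a flat fit."""


@dataclass(frozen=True)
class SigmoidFit:
    """Logistic fit v(t) = v_i + (v_f - v_i)/(1 + exp(-(t - t50)/scale)).

    Times are seconds after the light step.  ``v_initial`` is fixed from
    the pre-step window, not fitted.  ``degenerate`` marks flat traces
    (v_f ~ v_i) whose t50 is meaningless.
    """

    variable: str
    v_initial: float
    v_final: float
    t50: float
    slope_scale: float
    rmse: float
    degenerate: bool = False

    def predict(self, t_after_step):
        t = np.asarray(t_after_step, dtype=float)
        out = self.v_initial + (self.v_final - self.v_initial) / (
            1.0 + np.exp(-(t - self.t50) / self.slope_scale)
        )
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "v_initial": self.v_initial,
            "v_final": self.v_final,
            "t50": self.t50,
            "slope_scale": self.slope_scale,
            "rmse": self.rmse,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class LimitationCourse:
    """Time courses of biochemical (BL) and diffusional (DL) limitation."""

    time: np.ndarray  # s after step
    BL: np.ndarray
    DL: np.ndarray
    skipped: np.ndarray  # records dropped (Ci <= gamma_star)
    A_f: float
    Ci_f: float

    @property
    def mean_BL(self) -> float:
        return float(np.mean(self.BL))

    @property
    def mean_DL(self) -> float:
        return float(np.mean(self.DL))


@dataclass(frozen=True)
class InductionResult:
    """Full summary of one step-change induction experiment."""

    fit_A: SigmoidFit
    fit_gs: SigmoidFit
    ccf: float  # mmol CO2 m-2 over the horizon
    horizon: float  # s
    it50: float
    it90: float
    limitation: LimitationCourse | None
    mean_iwue: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "fit_A": self.fit_A.to_dict(),
            "fit_gs": self.fit_gs.to_dict(),
            "ccf_mmol_m2": self.ccf,
            "horizon_s": self.horizon,
            "it50_s": self.it50,
            "it90_s": self.it90,
            "mean_iwue": self.mean_iwue,
            "metadata": {k: v for k, v in self.metadata.items()
                         if isinstance(v, (int, float, str, bool))},
        }
        if self.limitation is not None:
            d["mean_BL"] = self.limitation.mean_BL
            d["mean_DL"] = self.limitation.mean_DL
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def report(self) -> str:
        flat = {}
        d = self.to_dict()
        for k, v in d.items():
            if isinstance(v, dict):
                flat.update({f"{k}.{k2}": v2 for k2, v2 in v.items()})
            else:
                flat[k] = v
        return "\n".join(f"{k}={v}" for k, v in flat.items())


def fit_induction_sigmoid(
    trace: GasExchangeTrace,
    variable: str,
    t_step: float,
    flat_tol: float = 1e-3,
    n_restarts: int = 5,
) -> SigmoidFit:
    """Fit the induction logistic to A(t) or gs(t) after a light step.

    ``v_initial`` is fixed to the mean of the pre-step records; v_final,
    t50 and the slope scale are estimated by least squares on the
    post-step records.  A trace whose post-step rise is below ``flat_tol``
    (relative to |v_i| + 1) is flagged degenerate.
    """
    if variable not in ("A", "gs"):
        raise ValueError("variable must be 'A' or 'gs'")
    t = trace.time
    v = trace.column(variable)
    pre = t < t_step
    post = ~pre
    if not pre.any():
        raise ValueError("no pre-step records to fix v_initial")
    if t[post][-1] - t_step < 300.0:
        raise ValueError("trace must span at least 5 min after the step")
    v_i = float(np.mean(v[pre]))
    tt = t[post] - t_step
    vv = v[post]

    rise = float(np.max(vv) - v_i)
    if abs(rise) < flat_tol * (abs(v_i) + 1.0):
        return SigmoidFit(variable, v_i, v_i, math.nan, math.nan,
                          float(np.std(vv - v_i)), degenerate=True)

    def model(x, t_):
        vf, t50, sc = x
        z = np.clip(-(t_ - t50) / sc, -500.0, 500.0)
        return v_i + (vf - v_i) / (1.0 + np.exp(z))

    def resid(x):
        return model(x, tt) - vv

    span = float(tt[-1])
    # deterministic multi-start over t50/scale guesses
    guesses = [
        (float(np.mean(vv[tt > 0.8 * span])), f_t * span, f_s * span)
        for f_t in (0.1, 0.25, 0.5)
        for f_s in (0.05, 0.15)
    ][: max(1, n_restarts + 1)]
    best = None
    for x0 in guesses:
        try:
            sol = optimize.least_squares(
                resid, x0=list(x0),
                bounds=([-1e4, 0.0, 1e-3], [1e4, 10.0 * span, 10.0 * span]),
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError(
            f"induction sigmoid fit for {variable} failed to converge "
            f"after {len(guesses)} starts"
        )
    vf, t50, sc = (float(z) for z in best.x)
    rmse = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return SigmoidFit(variable, v_i, vf, t50, sc, rmse)


def cumulative_fixation(
    trace: GasExchangeTrace,
    t_step: float,
    horizon: float = 600.0,
    method: str = "trapezoid",
) -> float:
    """Cumulative CO2 fixation over [t_step, t_step + horizon], mmol m-2.

    Integrates the measured A (not a fitted curve); negative transients
    are retained.  ``method`` is ``trapezoid`` (default) or ``rectangle``
    (left-Riemann at the sampling interval).
    """
    t = trace.time
    a = trace.column("A")
    t_end = t_step + horizon
    dt_med = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    if t[0] > t_step + 1e-9 or t[-1] < t_end - dt_med - 1e-9:
        raise ValueError(
            f"trace [{t[0]}, {t[-1]}] does not cover the horizon "
            f"[{t_step}, {t_end}]"
        )
    mask = (t >= t_step - 1e-9) & (t <= t_end + 1e-9)
    tt, aa = t[mask], a[mask]
    if method == "trapezoid":
        total = float(np.trapezoid(aa, tt))
    elif method == "rectangle":
        total = float(np.sum(aa[:-1] * np.diff(tt)))
    else:
        raise ValueError("method must be 'trapezoid' or 'rectangle'")
    return total * 1e-3  # umol -> mmol


def induction_time(fit: SigmoidFit, fraction: float) -> float:
    """Time after the step at which the fitted rise reaches ``fraction``.

    For the logistic this is t50 + scale*ln(f/(1-f)).
    """
    if fit.degenerate:
        raise DegenerateFitError(
            f"induction time undefined for degenerate {fit.variable} fit"
        )
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    return fit.t50 + fit.slope_scale * math.log(fraction / (1.0 - fraction))


def limitation_partition(
    trace: GasExchangeTrace,
    kin: LeafKinetics | None = None,
    t_step: float = 0.0,
    steady_window: float = 120.0,
) -> LimitationCourse:
    """Partition the induction shortfall into diffusional and biochemical.

    Steady-state end values A_f and Ci_f are means over the final
    ``steady_window`` seconds.  Records with Ci(t) <= gamma_star carry no
    Rubisco-limited information and are skipped with a flag.
    """
    kin = kin or LeafKinetics()
    t = trace.time
    a = trace.column("A")
    ci = trace.column("Ci")
    post = t >= t_step
    t_p, a_p, ci_p = t[post], a[post], ci[post]
    if len(t_p) == 0:
        raise ValueError("no records after the step")
    tail = t_p >= t_p[-1] - steady_window
    a_f = float(np.mean(a_p[tail]))
    ci_f = float(np.mean(ci_p[tail]))
    if a_f <= 0:
        raise ValueError(f"steady-state A_f = {a_f:.3f} <= 0; cannot partition")

    keep = ci_p > kin.gamma_star
    demand_f = (ci_f - kin.gamma_star) / (ci_f + kin.Km)
    demand_t = (ci_p[keep] - kin.gamma_star) / (ci_p[keep] + kin.Km)
    a_star = a_p[keep] * demand_f / demand_t
    dl = (a_star - a_p[keep]) / a_f
    bl = (a_f - a_star) / a_f
    return LimitationCourse(
        time=t_p[keep] - t_step,
        BL=bl,
        DL=dl,
        skipped=t_p[~keep] - t_step,
        A_f=a_f,
        Ci_f=ci_f,
    )


def iwue(A, gs):
    """Intrinsic water-use efficiency A/gs, umol CO2 (mol H2O)-1."""
    A = np.asarray(A, dtype=float)
    gs = np.asarray(gs, dtype=float)
    if np.any(gs <= 0):
        raise ValueError("gs must be strictly positive")
    out = A / gs
    return out if out.ndim else float(out)


def _time_weighted_mean(t: np.ndarray, v: np.ndarray) -> float:
    if len(t) == 1:
        return float(v[0])
    return float(np.trapezoid(v, t) / (t[-1] - t[0]))


def analyze_induction(
    trace: GasExchangeTrace,
    t_step: float,
    kin: LeafKinetics | None = None,
    horizon: float = 600.0,
    steady_window: float = 120.0,
) -> InductionResult:
    """Run the full induction analysis on one step-change trace."""
    kin = kin or LeafKinetics()
    fit_a = fit_induction_sigmoid(trace, "A", t_step)
    fit_gs = fit_induction_sigmoid(trace, "gs", t_step)
    ccf = cumulative_fixation(trace, t_step, horizon=horizon)
    if fit_a.degenerate:
        it50 = it90 = math.nan
    else:
        it50 = induction_time(fit_a, 0.5)
        it90 = induction_time(fit_a, 0.9)
    try:
        lim = limitation_partition(trace, kin, t_step, steady_window)
    except ValueError:
        lim = None
    post = trace.time >= t_step
    mean_wue = _time_weighted_mean(
        trace.time[post],
        np.asarray(iwue(trace.column("A")[post], trace.column("gs")[post])),
    )
    return InductionResult(
        fit_A=fit_a,
        fit_gs=fit_gs,
        ccf=ccf,
        horizon=horizon,
        it50=it50,
        it90=it90,
        limitation=lim,
        mean_iwue=mean_wue,
        metadata=dict(trace.metadata),
    )
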