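"""Steady-state FvCB photosynthesis model and A-Ci curve fitting.

The Farquhar-von Caemmerer-Berry (FvCB) model describes net CO2
assimilation ``A`` of a C3 leaf as the minimum of two potential rates:

* a Rubisco-limited (carboxylation-limited) rate ``Ac``, governed by the
  maximum carboxylation capacity ``Vcmax``, and
* an RuBP-regeneration-limited rate ``Aj``, governed by the electron
  transport rate ``J``, itself capped by the capacity ``Jmax``.

Both rates share the CO2 compensation point ``gamma_star`` and the day
respiration ``Rd``.  Fitting the model to an A-Ci response curve measured
at saturating light yields estimates of ``Vcmax`` and ``Jmax`` and of
their ratio, a standard index of the balance between carboxylation and
electron-transport capacity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "LeafKinetics",
    "FvCBParams",
    "ACiCurve",
    "ACiFit",
    "FitDegenerateError",
    "FitConvergenceError",
    "rubisco_limited_rate",
    "j_light_response",
    "rubp_limited_rate",
    "net_assimilation",
    "fit_aci",
    "jmax_vcmax_ratio",
]


@dataclass(frozen=True)
class LeafKinetics:
    """Biochemical constants of the FvCB model at a fixed leaf temperature.

    Defaults are rice-leaf values at 30 degC.  ``Kc`` and ``Ko`` are
    Michaelis constants for CO2 and O2 expressed as mole fractions
    (umol mol-1 and mmol mol-1); ``gamma_star`` is the CO2 compensation
    point without day respiration (umol mol-1); ``Rd`` is day respiration
    (umol m-2 s-1); ``O`` is the ambient O2 mole fraction (mmol mol-1).
    """

    Kc: float = 690.05
    Ko: float = 353.02
    gamma_star: float = 55.22
    Rd: float = 1.37
    O: float = 210.0

    def __post_init__(self) -> None:
        for name in ("Kc", "Ko", "gamma_star", "Rd", "O"):
            if getattr(self, name) <= 0:
                raise ValueError(f"LeafKinetics.{name} must be strictly positive")

    @property
    def Km(self) -> float:
        """Effective Michaelis constant Kc*(1 + O/Ko), umol mol-1."""
        return self.Kc * (1.0 + self.O / self.Ko)


@dataclass(frozen=True)
class FvCBParams:
    """Leaf photosynthetic capacities and light-response shape.

    Vcmax, Jmax in umol m-2 s-1; ``theta`` is the curvature of the
    non-rectangular hyperbola for J(PPFD), ``alpha`` its initial quantum
    yield in mol electrons per mol photons.
    """

    Vcmax: float
    Jmax: float
    theta: float = 0.7
    alpha: float = 0.3

    def __post_init__(self) -> None:
        if self.Vcmax <= 0 or self.Jmax <= 0:
            raise ValueError("Vcmax and Jmax must be strictly positive")
        if not (0.0 < self.theta <= 1.0):
            raise ValueError("theta must lie in (0, 1]")
        if not (0.0 < self.alpha < 0.5):
            raise ValueError("alpha must lie in (0, 0.5)")


@dataclass(frozen=True)
class ACiCurve:
    """An A-Ci response curve: (Ci, A) points measured at one irradiance."""

    ci: tuple[float, ...]
    a: tuple[float, ...]
    ppfd: float = 1500.0
    leaf_temp: float = 30.0

    def __post_init__(self) -> None:
        ci = tuple(float(x) for x in self.ci)
        a = tuple(float(x) for x in self.a)
        object.__setattr__(self, "ci", ci)
        object.__setattr__(self, "a", a)
        if len(ci) != len(a):
            raise ValueError("ci and a must have equal length")
        if len(ci) < 5:
            raise ValueError("an A-Ci curve needs at least 5 points")
        if any(x <= 0 for x in ci):
            raise ValueError("all Ci values must be strictly positive")
        if any(b <= x for x, b in zip(ci, ci[1:])):
            raise ValueError("Ci values must be strictly increasing")

    @classmethod
    def from_points(
        cls,
        points: Sequence[tuple[float, float]],
        ppfd: float = 1500.0,
        leaf_temp: float = 30.0,
    ) -> "ACiCurve":
        pts = sorted((float(c), float(a)) for c, a in points)
        return cls(
            ci=tuple(p[0] for p in pts),
            a=tuple(p[1] for p in pts),
            ppfd=ppfd,
            leaf_temp=leaf_temp,
        )

    def __len__(self) -> int:
        return len(self.ci)


@dataclass(frozen=True)
class ACiFit:
    """Result of fitting the FvCB minimum-rule model to an A-Ci curve."""

    params: FvCBParams
    ci_transition: float
    rmse: float
    n_rubisco_pts: int
    n_rubp_pts: int
    jmax_vcmax_ratio: float
    transition_in_range: bool = True
    n_iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "Vcmax": self.params.Vcmax,
            "Jmax": self.params.Jmax,
            "theta": self.params.theta,
            "alpha": self.params.alpha,
            "ci_transition": self.ci_transition,
            "rmse": self.rmse,
            "n_rubisco_pts": self.n_rubisco_pts,
            "n_rubp_pts": self.n_rubp_pts,
            "jmax_vcmax_ratio": self.jmax_vcmax_ratio,
            "transition_in_range": self.transition_in_range,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def report(self) -> str:
        """Flat key=value report."""
        return "\n".join(f"{k}={v}" for k, v in self.to_dict().items())


class FitDegenerateError(ValueError):
    """Raised when a branch of the segmented fit has too few points."""

    def __init__(self, branch: str, n: int):
        self.branch = branch
        self.n = n
        super().__init__(
            f"fit degenerate: only {n} point(s) assignable to the "
            f"{branch} branch (need >= 3)"
        )


class FitConvergenceError(RuntimeError):
    """Raised when the segmented fit fails to converge."""


def rubisco_limited_rate(ci, params: FvCBParams, kin: LeafKinetics):
    """Rubisco-limited net assimilation Ac, umol m-2 s-1.

    Ac = Vcmax * (Ci - gamma_star) / (Ci + Km) - Rd with
    Km = Kc * (1 + O/Ko).  Strictly increasing in Ci, saturating
    toward Vcmax - Rd.
    """
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= 0):
        raise ValueError("ci must be strictly positive")
    out = params.Vcmax * (ci - kin.gamma_star) / (ci + kin.Km) - kin.Rd
    return out if out.ndim else float(out)


def j_light_response(ppfd, params: FvCBParams):
    """Electron transport rate J(PPFD), umol e- m-2 s-1.

    Non-rectangular hyperbola: the smaller root of
    ``theta*J^2 - (alpha*I + Jmax)*J + alpha*I*Jmax = 0``.
    J(0) = 0, J is non-decreasing and bounded by Jmax.
    """
    i = np.asarray(ppfd, dtype=float)
    if np.any(i < 0):
        raise ValueError("ppfd must be non-negative")
    ai = params.alpha * i
    b = ai + params.Jmax
    disc = b * b - 4.0 * params.theta * ai * params.Jmax
    j = (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * params.theta)
    return j if j.ndim else float(j)


def rubp_limited_rate(ci, j, kin: LeafKinetics):
    """RuBP-regeneration-limited net assimilation Aj, umol m-2 s-1.

    Aj = J * (Ci - gamma_star) / (4*Ci + 8*gamma_star) - Rd.
    Asymptote J/4 - Rd as Ci grows.
    """
    ci = np.asarray(ci, dtype=float)
    j = np.asarray(j, dtype=float)
    if np.any(ci <= 0):
        raise ValueError("ci must be strictly positive")
    if np.any(j < 0):
        raise ValueError("j must be non-negative")
    out = j * (ci - kin.gamma_star) / (4.0 * ci + 8.0 * kin.gamma_star) - kin.Rd
    return out if out.ndim else float(out)


def net_assimilation(ci, ppfd, params: FvCBParams, kin: LeafKinetics):
    """Net assimilation under the FvCB minimum rule, umol m-2 s-1."""
    ac = rubisco_limited_rate(ci, params, kin)
    aj = rubp_limited_rate(ci, j_light_response(ppfd, params), kin)
    out = np.minimum(ac, aj)
    return out if np.ndim(out) else float(out)


def ci_transition_point(params: FvCBParams, j: float, kin: LeafKinetics) -> float:
    """Ci at which Ac = Aj for the given J; nan if no crossing exists.

    Solving Vcmax*(Ci-G)/(Ci+Km) = J*(Ci-G)/(4Ci+8G) gives
    Ci = (J*Km - 8*G*Vcmax) / (4*Vcmax - J).
    """
    denom = 4.0 * params.Vcmax - j
    if denom <= 0:
        return math.nan
    ci_t = (j * kin.Km - 8.0 * kin.gamma_star * params.Vcmax) / denom
    return ci_t if ci_t > 0 else math.nan


def _init_vcmax(ci: np.ndarray, a: np.ndarray, kin: LeafKinetics) -> float:
    # invert Ac at the 3 lowest-Ci points with Ci above the compensation point
    usable = ci > kin.gamma_star * 1.05
    ci_u, a_u = ci[usable][:3], a[usable][:3]
    if len(ci_u) == 0:
        return 50.0
    est = (a_u + kin.Rd) * (ci_u + kin.Km) / (ci_u - kin.gamma_star)
    est = est[est > 0]
    return float(np.median(est)) if len(est) else 50.0


def _fit_branch_scalar(resid_fn, x0: float) -> float:
    sol = optimize.least_squares(resid_fn, x0=[x0], bounds=([1e-3], [1e4]))
    return float(sol.x[0])


def fit_aci(
    curve: ACiCurve,
    kin: LeafKinetics | None = None,
    theta: float = 0.7,
    alpha: float = 0.3,
    max_iter: int = 20,
) -> ACiFit:
    """Fit Vcmax and Jmax to an A-Ci curve by segmented least squares.

    Each point is assigned to the FvCB branch (Rubisco- or RuBP-limited)
    that is minimal under the current parameters; each branch parameter is
    then refit to its points, and the assignment is iterated to stability
    (at most ``max_iter`` rounds).  Vcmax is initialised by inverting the
    Rubisco-limited equation at the lowest-Ci points and Jmax at
    1.5*Vcmax.  The RuBP branch is evaluated at J(curve.ppfd), so the
    reported Jmax is the light-response capacity consistent with the
    measurement irradiance.

    Raises
    ------
    FitDegenerateError
        if fewer than 3 points are assignable to a branch at the solution.
    FitConvergenceError
        if the branch assignment does not stabilise.
    """
    kin = kin or LeafKinetics()
    ci = np.asarray(curve.ci)
    a = np.asarray(curve.a)

    vcmax = _init_vcmax(ci, a, kin)
    jmax = 1.5 * vcmax

    def branch_rates(vc: float, jm: float) -> tuple[np.ndarray, np.ndarray]:
        p = FvCBParams(vc, jm, theta=theta, alpha=alpha)
        ac = rubisco_limited_rate(ci, p, kin)
        aj = rubp_limited_rate(ci, j_light_response(curve.ppfd, p), kin)
        return np.asarray(ac), np.asarray(aj)

    assignment = None
    seen: set[bytes] = set()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ac, aj = branch_rates(vcmax, jmax)
        new_assignment = ac <= aj  # True -> Rubisco-limited branch
        if assignment is not None and np.array_equal(new_assignment, assignment):
            break
        key = np.packbits(new_assignment).tobytes()
        if key in seen:
            # boundary point oscillating between branches: accept; the
            # joint minimum-rule polish below resolves the tie
            assignment = new_assignment
            break
        seen.add(key)
        assignment = new_assignment

        rub = assignment
        rubp = ~assignment
        if rub.sum() >= 2:
            ci_r, a_r = ci[rub], a[rub]

            def resid_vc(x, _ci=ci_r, _a=a_r):
                return x[0] * (_ci - kin.gamma_star) / (_ci + kin.Km) - kin.Rd - _a

            vcmax = _fit_branch_scalar(resid_vc, vcmax)
        if rubp.sum() >= 2:
            ci_j, a_j = ci[rubp], a[rubp]

            def resid_jm(x, _ci=ci_j, _a=a_j):
                p = FvCBParams(vcmax, x[0], theta=theta, alpha=alpha)
                j = j_light_response(curve.ppfd, p)
                return (
                    j * (_ci - kin.gamma_star) / (4.0 * _ci + 8.0 * kin.gamma_star)
                    - kin.Rd
                    - _a
                )

            jmax = _fit_branch_scalar(resid_jm, jmax)
    else:
        raise FitConvergenceError(
            f"branch assignment did not stabilise within {max_iter} iterations "
            f"(Vcmax={vcmax:.2f}, Jmax={jmax:.2f})"
        )

    n_rub = int(assignment.sum())
    n_rubp = int((~assignment).sum())
    if n_rub < 3:
        raise FitDegenerateError("Rubisco", n_rub)
    if n_rubp < 3:
        raise FitDegenerateError("RuBP", n_rubp)

    # joint polish on the minimum-rule model from the segmented solution
    def resid_joint(x):
        p = FvCBParams(x[0], x[1], theta=theta, alpha=alpha)
        return np.asarray(net_assimilation(ci, curve.ppfd, p, kin)) - a

    sol = optimize.least_squares(
        resid_joint, x0=[vcmax, jmax], bounds=([1e-3, 1e-3], [1e4, 1e4])
    )
    vcmax, jmax = float(sol.x[0]), float(sol.x[1])

    params = FvCBParams(vcmax, jmax, theta=theta, alpha=alpha)
    j_meas = j_light_response(curve.ppfd, params)
    resid = resid_joint([vcmax, jmax])
    rmse = float(np.sqrt(np.mean(resid**2)))
    ci_t = ci_transition_point(params, j_meas, kin)
    in_range = bool(np.isfinite(ci_t) and ci[0] <= ci_t <= ci[-1])

    return ACiFit(
        params=params,
        ci_transition=ci_t,
        rmse=rmse,
        n_rubisco_pts=n_rub,
        n_rubp_pts=n_rubp,
        jmax_vcmax_ratio=jmax / vcmax,
        transition_in_range=in_range,
        n_iterations=n_iter,
    )


def jmax_vcmax_ratio(fit: ACiFit) -> float:
    """Jmax/Vcmax of a fit (dimensionless; summaries print 2 decimals)."""
    return fit.params.Jmax / fit.params.Vcmax
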