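"""Two-dimensional mean-field model of rate dynamics under homeostatic
triplet plasticity, with closed-form stability analysis.

State: the population rate ``r`` and the homeostatic rate estimate ``rbar``
(the low-pass filtered rate, time constant ``tau_bar``).

The static network response is linearised as ``r = F0 / (1 - F1 w)`` (offset
``F0``, dimensionless recurrent gain ``F1 w``); averaging the triplet rule
over uncorrelated Poisson statistics gives the BCM-type rate rule

    dw/dt = eta * w0 / (tau_w * kappa**3) * r_pre * r_post * (r_post - gamma(rbar))

with the sliding threshold ``gamma(rbar) = kappa * (rbar/kappa)**beta`` and
the effective plasticity timescale ``tau_w = 1/(A3+ tau+ tau_y kappa**3)``.
Chaining the two through ``dr/dt = (dr/dw) (dw/dt)`` yields a closed flow in
``(r, rbar)`` with a quiescent fixed point at the origin and the background
fixed point at ``(kappa, kappa)``.

Three variants share this skeleton: the metaplastic rule above, the same
rule plus a slow weight decay (``decay_rate = 1/tau_decay``), and triplet
STDP with a fixed LTD threshold plus multiplicative synaptic scaling
(timescale ``tau_scaling``, exponent ``scaling_exponent``).

The central result: the background state is linearly stable iff the rate
detector is fast enough, ``tau_bar < tau_crit`` with

    tau_crit = F0 * tau_w / (eta * w0 * F1 * kappa)

(metaplastic; independent of ``beta``).  A slow weight decay shifts
``tau_crit`` up slightly; synaptic scaling keeps the same condition as a
necessary one but additionally requires ``tau_scaling`` to stay below an
upper bound.  Because ``tau_w`` scales as ``kappa**-3`` the critical
timescale falls off as the fourth power of the background rate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import MFParams, TripletParams, ConfigurationError, VARIANTS
from .plasticity import ltd_amplitude

__all__ = [
    "MFState",
    "StabilityReport",
    "steady_rate",
    "poisson_drift",
    "bcm_fixed_point_rate",
    "effective_tau_w",
    "vector_field",
    "fixed_point",
    "jacobian_at_fixed_point",
    "eigenvalues",
    "critical_tau",
    "max_stable_tau_scaling",
    "stability_report",
    "classify_fate",
    "nullclines",
    "separatrix",
    "phase_portrait",
]


@dataclass(frozen=True)
class MFState:
    """State of the mean-field system: rate and rate estimate (Hz)."""

    r: float
    r_bar: float

    def __post_init__(self):
        if self.r < 0 or self.r_bar < 0:
            raise ConfigurationError("rates must be nonnegative")


@dataclass(frozen=True)
class StabilityReport:
    """Linear stability of the background fixed point."""

    fixed_point: Tuple[float, float]
    eigenvalues: Tuple[complex, complex]
    tau_crit: float
    stable: bool
    variant: str
    tau_scaling_max: Optional[float] = None


# ----------------------------------------------------------------- statics

def steady_rate(w: float, params: MFParams) -> float:
    """Self-consistent population rate of the static network,
    ``r = F0 / (1 - F1 w)``; diverges at the response pole ``F1 w = 1``."""
    x = params.F1 * w
    if x >= 1.0:
        raise ConfigurationError(
            f"F1*w = {x:.4g} >= 1: network response pole reached")
    return params.F0 / (1.0 - x)


def poisson_drift(r_pre: float, r_post: float, r_bar: float,
                  triplet: TripletParams, beta: float = 2.0,
                  metaplastic: bool = True) -> float:
    """Closed-form expected weight drift (per second) of the triplet rule
    for independent Poisson pre/post trains.

    LTP: each post spike (rate ``y``) reads the mean presynaptic fast trace
    ``x tau_plus`` and the mean slow trace just before the spike
    ``y tau_y``.  LTD: each pre spike (rate ``x``) reads the mean fast
    postsynaptic trace ``y tau_minus``.
    """
    p = triplet
    if metaplastic:
        a2 = ltd_amplitude(r_bar, p, beta)
    else:
        a2 = p.A2_minus_ref
    ltp = p.A3_plus * p.tau_plus * p.tau_y * r_pre * r_post ** 2
    ltd = a2 * p.tau_minus * r_pre * r_post
    return p.eta * p.w0 * (ltp - ltd)


def bcm_fixed_point_rate(triplet: TripletParams, beta: float = 2.0,
                         r_max: float = 100.0) -> float:
    """The positive firing rate at which the expected metaplastic drift
    vanishes when pre rate = post rate = rate estimate.

    This is the nontrivial fixed point of the rule: below it LTD wins,
    above it LTP wins (the BCM property)."""
    def drift(r):
        return poisson_drift(r, r, r, triplet, beta=beta)
    lo = 1e-3
    hi = None
    for r in np.linspace(lo, r_max, 2000):
        if drift(lo) * drift(r) < 0:
            hi = r
            break
    if hi is None:
        raise ConfigurationError("no drift zero crossing found below r_max")
    return float(brentq(drift, lo, hi, xtol=1e-12, rtol=1e-14))


def effective_tau_w(triplet: TripletParams, kappa: Optional[float] = None) -> float:
    """Effective timescale of plasticity from the Poisson-averaged rule,
    ``tau_w = 1 / (A3_plus tau_plus tau_y kappa**3)`` (about 3000 s at
    3 Hz for the visual-cortex parameter set)."""
    k = triplet.kappa if kappa is None else kappa
    return 1.0 / (triplet.A3_plus * triplet.tau_plus * triplet.tau_y * k ** 3)


# ------------------------------------------------------------------- flows

def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}")


def _C(p: MFParams) -> float:
    # prefactor of the rate flow: dr/dt = C r^4 (r - threshold) + ...
    return p.eta * p.w0 * p.F1 / (p.F0 * p.tau_w * p.kappa ** 3)


def _gamma(r_bar: float, p: MFParams) -> float:
    return p.kappa * (r_bar / p.kappa) ** p.beta


def vector_field(state: MFState, params: MFParams, variant: str,
                 ) -> Tuple[float, float]:
    """Right-hand side ``(dr/dt, drbar/dt)`` of the selected variant."""
    _check_variant(variant)
    r, rb = state.r, state.r_bar
    p = params
    C = _C(p)
    if variant == "metaplastic_ltd":
        dr = C * r ** 4 * (r - _gamma(rb, p))
    elif variant == "weight_decay":
        dr = C * r ** 4 * (r - _gamma(rb, p)) \
            - p.decay_rate * r * (r - p.F0) / p.F0
    else:  # synaptic_scaling
        n = p.scaling_exponent
        h = 1.0 - (rb / p.kappa) ** n
        dr = C * r ** 4 * (r - p.kappa) \
            + r * (r - p.F0) * h / (p.F0 * p.tau_scaling)
    drb = (r - rb) / p.tau_bar
    return dr, drb


def fixed_point(params: MFParams, variant: str) -> Tuple[float, float]:
    """Background fixed point ``(r*, r*)``.

    Exactly ``(kappa, kappa)`` for the metaplastic and scaling variants; a
    slow weight decay pulls it slightly below ``kappa`` (solved
    numerically on the diagonal)."""
    _check_variant(variant)
    p = params
    if variant in ("metaplastic_ltd", "synaptic_scaling") or p.decay_rate == 0.0:
        return (p.kappa, p.kappa)

    # slow decay shifts the background fixed point slightly below kappa;
    # take the diagonal root closest to kappa (lower roots are saddles on
    # the boundary of the quiescent basin)
    def f(r):
        return vector_field(MFState(r, r), p, variant)[0]

    lo_lim = p.F0 * (1 + 1e-9)
    grid = np.linspace(p.kappa, lo_lim, 512)
    vals = np.array([f(r) for r in grid])
    if vals[0] >= 0:
        raise ConfigurationError("flow at kappa must be negative with decay on")
    crossings = np.flatnonzero(np.sign(vals[1:]) != np.sign(vals[:-1]))
    if crossings.size == 0:
        raise ConfigurationError(
            "no background fixed point between F0 and kappa for this decay rate")
    i = crossings[0]
    r_star = brentq(f, grid[i + 1], grid[i], xtol=1e-14, rtol=1e-15)
    return (float(r_star), float(r_star))


def jacobian_at_fixed_point(params: MFParams, variant: str) -> np.ndarray:
    """Closed-form Jacobian of the flow at the background fixed point."""
    _check_variant(variant)
    p = params
    r, rb = fixed_point(p, variant)
    C = _C(p)
    if variant == "synaptic_scaling":
        n = p.scaling_exponent
        df_dr = C * (4 * r ** 3 * (r - p.kappa) + r ** 4)
        df_drb = -r * (r - p.F0) * n / (p.kappa * p.F0 * p.tau_scaling) \
            * (rb / p.kappa) ** (n - 1)
    else:
        gamma = _gamma(rb, p)
        df_dr = C * (4 * r ** 3 * (r - gamma) + r ** 4)
        df_drb = -C * r ** 4 * p.beta * (rb / p.kappa) ** (p.beta - 1)
        if variant == "weight_decay":
            df_dr -= p.decay_rate * (2 * r - p.F0) / p.F0
    return np.array([[df_dr, df_drb],
                     [1.0 / p.tau_bar, -1.0 / p.tau_bar]])


def eigenvalues(params: MFParams, variant: str) -> Tuple[complex, complex]:
    """Closed-form eigenvalue pair of the linearised system,
    ``lambda = T/2 +- sqrt(T^2/4 - D)`` with trace ``T`` and determinant
    ``D`` of the Jacobian."""
    J = jacobian_at_fixed_point(params, variant)
    T = J[0, 0] + J[1, 1]
    D = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    disc = complex(T * T / 4.0 - D)
    root = np.sqrt(disc)
    return (T / 2.0 + root, T / 2.0 - root)


def critical_tau(params: MFParams, variant: str) -> float:
    """Critical rate-detector timescale ``tau_crit``.

    The trace of the Jacobian is ``df/dr - 1/tau_bar``, so the stability
    boundary sits at ``tau_crit = 1 / (df/dr)`` evaluated at the fixed
    point; for the metaplastic rule this reduces to
    ``F0 tau_w / (eta w0 F1 kappa)`` and is independent of ``beta``.  For
    synaptic scaling the same expression is necessary but not sufficient
    (see :func:`max_stable_tau_scaling`).  Returns ``inf`` when the flow is
    contracting for every detector timescale.
    """
    _check_variant(variant)
    p = params
    if variant == "metaplastic_ltd":
        df_dr = _C(p) * p.kappa ** 4
    else:
        # same trace argument, evaluated at the (possibly shifted) fixed point
        r, rb = fixed_point(p, variant)
        J = jacobian_at_fixed_point(p.replace(tau_bar=1.0), variant)
        df_dr = J[0, 0]
    if df_dr <= 0:
        return np.inf
    return 1.0 / df_dr


def max_stable_tau_scaling(params: MFParams) -> float:
    """Upper bound on the synaptic-scaling timescale.

    At the fixed point ``det J = (b - a)/tau_bar`` with ``a = df/dr`` and
    ``b = |df/drbar| = n (kappa - F0) / (F0 tau_scaling)``; a saddle
    (instability regardless of ``tau_bar``) appears once ``b < a``, i.e.
    for ``tau_scaling > n (kappa - F0) tau_crit / F0``."""
    p = params
    a = _C(p) * p.kappa ** 4
    return p.scaling_exponent * (p.kappa - p.F0) / (p.F0 * a)


def stability_report(params: MFParams, variant: str) -> StabilityReport:
    lam = eigenvalues(params, variant)
    tc = critical_tau(params, variant)
    stable = bool(max(l.real for l in lam) < 0)
    extra = max_stable_tau_scaling(params) if variant == "synaptic_scaling" else None
    return StabilityReport(fixed_point=fixed_point(params, variant),
                           eigenvalues=lam, tau_crit=tc, stable=stable,
                           variant=variant, tau_scaling_max=extra)


# ------------------------------------------------------------- phase plane

def _rhs(params: MFParams, variant: str) -> Callable:
    def fun(t, y):
        r = max(y[0], 0.0)
        rb = max(y[1], 0.0)
        return vector_field(MFState(r, rb), params, variant)
    return fun


def classify_fate(params: MFParams, variant: str, ic: Tuple[float, float],
                  t_max: float = 5000.0, div_radius_factor: float = 100.0,
                  conv_tol: float = 1e-3) -> str:
    """Long-time fate of an initial condition: ``converged`` (to the
    background fixed point), ``diverged`` (left the admissible domain) or
    ``undecided``."""
    fp = fixed_point(params, variant)
    R = div_radius_factor * params.kappa

    def diverge(t, y):
        return max(y) - R
    diverge.terminal = True
    diverge.direction = 1.0

    sol = solve_ivp(_rhs(params, variant), (0.0, t_max), list(ic),
                    rtol=1e-8, atol=1e-10, events=diverge, method="RK45")
    if sol.t_events[0].size:
        return "diverged"
    end = sol.y[:, -1]
    if np.hypot(end[0] - fp[0], end[1] - fp[1]) < conv_tol * params.kappa:
        return "converged"
    return "undecided"


def nullclines(params: MFParams, variant: str, r_grid: np.ndarray,
               ) -> Dict[str, np.ndarray]:
    """Zero-level sets of the two flow components.

    The ``rbar``-nullcline is the diagonal ``rbar = r``; the ``r``-nullcline
    is solved for ``rbar`` as a function of ``r`` (NaN where no solution
    exists).  ``r = 0`` is always an ``r``-nullcline branch.
    """
    _check_variant(variant)
    p = params
    C = _C(p)
    r = np.asarray(r_grid, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "synaptic_scaling":
            n = p.scaling_exponent
            arg = 1.0 + C * r ** 4 * (r - p.kappa) * p.F0 * p.tau_scaling \
                / (r * (r - p.F0))
            rb = p.kappa * np.where(arg >= 0, arg, np.nan) ** (1.0 / n)
        else:
            target = r.copy()
            if variant == "weight_decay":
                target = r - p.decay_rate * (r - p.F0) / (p.F0 * C * r ** 3)
            arg = target / p.kappa
            rb = p.kappa * np.where(arg >= 0, arg, np.nan) ** (1.0 / p.beta)
    return {"r_nullcline_rbar": rb, "rbar_nullcline_rbar": r, "r": r}


def separatrix(params: MFParams, variant: str, n_rays: int = 24,
               t_max: float = 5000.0, s_max_factor: float = 50.0,
               tol: float = 1e-3) -> np.ndarray:
    """Basin boundary of the background fixed point by ray bisection.

    From the fixed point, each ray direction is bisected on the radius
    between the innermost diverging and outermost converging point (fate
    classified by long-time integration with a divergence radius of
    ``100 kappa``).  Returns an ``(n_rays, 2)`` array of boundary points
    (NaN rows where the whole ray converges up to ``s_max``).
    """
    p = params
    if critical_tau(p, variant) <= p.tau_bar:
        raise ConfigurationError("separatrix requires a stable background state")
    fp = np.array(fixed_point(p, variant))
    angles = np.linspace(0, 2 * np.pi, n_rays, endpoint=False)
    pts = np.full((n_rays, 2), np.nan)
    for k, th in enumerate(angles):
        d = np.array([np.cos(th), np.sin(th)])
        s_max = s_max_factor * p.kappa

        def fate(s):
            ic = fp + s * d
            if ic[0] < 0 or ic[1] < 0:
                return "diverged"  # outside the admissible quadrant
            return classify_fate(p, variant, tuple(ic), t_max=t_max)

        lo, hi = 0.0, None
        s = min(0.25 * p.kappa, s_max)
        while s <= s_max:
            f = fate(s)
            if f == "converged":
                lo = s
                s *= 2.0
            else:
                hi = s
                break
        if hi is None:
            continue  # converges along the whole probed ray
        while hi - lo > tol * p.kappa:
            mid = 0.5 * (lo + hi)
            if fate(mid) == "converged":
                lo = mid
            else:
                hi = mid
        pts[k] = fp + 0.5 * (lo + hi) * d
    return pts


@dataclass
class PhasePortrait:
    trajectories: List[Dict]
    nullclines: Dict[str, np.ndarray]
    fixed_point: Tuple[float, float]
    separatrix: Optional[np.ndarray] = None


def phase_portrait(params: MFParams, variant: str,
                   initial_conditions: Sequence[Tuple[float, float]],
                   t_max: float = 2000.0,
                   with_separatrix: bool = False,
                   r_grid: Optional[np.ndarray] = None) -> PhasePortrait:
    """Integrate trajectories (adaptive RK, rtol 1e-8), sample nullclines
    and optionally locate the separatrix."""
    p = params
    if r_grid is None:
        r_grid = np.linspace(1e-3, 4 * p.kappa, 400)
    trajs = []
    for ic in initial_conditions:
        fate = classify_fate(p, variant, ic, t_max=t_max)
        R = 100.0 * p.kappa

        def diverge(t, y):
            return max(y) - R
        diverge.terminal = True
        diverge.direction = 1.0
        sol = solve_ivp(_rhs(p, variant), (0.0, t_max), list(ic),
                        rtol=1e-8, atol=1e-10, events=diverge, dense_output=False)
        trajs.append({"ic": ic, "t": sol.t, "r": sol.y[0], "r_bar": sol.y[1],
                      "fate": fate})
    sep = separatrix(p, variant) if with_separatrix else None
    return PhasePortrait(trajectories=trajs,
                         nullclines=nullclines(p, variant, r_grid),
                         fixed_point=fixed_point(p, variant),
                         separatrix=sep)
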