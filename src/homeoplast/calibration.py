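"""Link the spiking network to the mean-field theory.

Two procedures: (1) measure the static network's rate response to a uniform
rescaling of the recurrent excitatory weights and fit the linearised
response ``r = F0/(1 - F1 w)`` to it; (2) sweep the rate-detector timescale
``tau_bar`` in full plastic simulations and locate the stability transition,
which the fitted mean-field theory should (over-)predict.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .params import (NetworkConfig, NeuronParams, TripletParams,
                     HomeostasisConfig, MFParams, ConfigurationError)
from .spikenet import (Network, build_network, simulate, detect_instability,
                       LifetimeResult)
from .meanfield import effective_tau_w

__all__ = [
    "FitResult",
    "TransitionEstimate",
    "scan_rate_response",
    "fit_linear_response",
    "mf_params_from_fit",
    "sweep_tau_critical",
]


@dataclass(frozen=True)
class FitResult:
    """Least-squares fit of the linearised network response."""

    F0: float
    F1: float
    interval: Tuple[float, float]
    residual: float  # mean squared error on the fit interval

    def predict(self, w: np.ndarray) -> np.ndarray:
        return self.F0 / (1.0 - self.F1 * np.asarray(w))


@dataclass(frozen=True)
class TransitionEstimate:
    """Location of the stability transition on a tau_bar grid."""

    value: float              # midpoint estimate (may be +-inf when censored)
    last_stable: float
    first_unstable: float
    censored: Optional[str]   # None | 'all_stable' | 'all_unstable'


def scan_rate_response(config: NetworkConfig,
                       w_values: Optional[Sequence[float]] = None,
                       settle: float = 20.0,
                       measure: float = 20.0,
                       neuron_params: NeuronParams = NeuronParams(),
                       dt: float = 1e-4,
                       seed: Optional[int] = None,
                       ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Steady-state excitatory rate as a function of the (uniform) EE weight.

    Plasticity is disabled.  For each weight the network runs ``settle``
    seconds and the rate is then averaged over ``measure`` seconds.  Points
    that run away are flagged with NaN rather than failing the scan.
    Returns ``(w, rate, sem)``.
    """
    if w_values is None:
        w_values = config.w_ee * np.linspace(0.7, 1.3, 9)
    w_values = np.asarray(sorted(w_values), dtype=float)
    net = build_network(config, seed=seed)
    rates = np.full(w_values.size, np.nan)
    sems = np.full(w_values.size, np.nan)
    guess = 3.0
    for i, w in enumerate(w_values):
        net.ee.data[:] = w
        try:
            res = simulate(net, neuron_params, duration=settle + measure, dt=dt,
                           seed=(seed if seed is not None else config.seed) + i,
                           record_raster=0, rate_window=1.0,
                           init_rates=(guess, 2.0 * guess),
                           abort_rate=150.0, stop_above=120.0)
        except Exception:
            continue
        if res.aborted_at is not None or res.duration < settle + measure - 1e-9:
            continue  # runaway point: flagged as NaN
        seg = res.rates.exc[res.rates.times > settle]
        rates[i] = seg.mean()
        sems[i] = seg.std(ddof=1) / np.sqrt(seg.size)
        if np.isfinite(rates[i]) and rates[i] > 0.2:
            guess = rates[i]
    net.ee.data[:] = config.w_ee
    return w_values, rates, sems


def fit_linear_response(w: np.ndarray, rates: np.ndarray,
                        interval: Optional[Tuple[float, float]] = None,
                        ) -> FitResult:
    """Nonlinear least squares of ``r(w) = F0 / (1 - F1 w)`` on an interval.

    The linearised response describes the balanced network well around the
    operating point but breaks down at high rates where refractory effects
    enter, hence the restricted fit interval.
    """
    w = np.asarray(w, dtype=float)
    rates = np.asarray(rates, dtype=float)
    ok = np.isfinite(rates)
    if interval is not None:
        ok &= (w >= interval[0]) & (w <= interval[1])
    else:
        interval = (float(w[ok].min()), float(w[ok].max()))
    if ok.sum() < 4:
        raise ConfigurationError("need at least 4 finite scan points in the interval")
    wf, rf = w[ok], rates[ok]

    def model(x, F0, F1):
        return F0 / (1.0 - F1 * x)

    # initial guess from the two endpoints
    F1_0 = max((1.0 - rf[0] / rf[-1]) / (wf[-1] - rf[0] / rf[-1] * wf[0] + 1e-12), 0.1)
    F0_0 = rf[0] * (1.0 - F1_0 * wf[0])
    try:
        popt, _ = curve_fit(model, wf, rf, p0=(max(F0_0, 1e-3), F1_0),
                            maxfev=20000)
    except RuntimeError as err:
        raise ConfigurationError(
            f"response fit did not converge: {err}; data w={wf}, r={rf}") from err
    F0, F1 = float(popt[0]), float(popt[1])
    if F0 <= 0 or np.any(F1 * wf >= 1.0):
        raise ConfigurationError(
            f"fit left the admissible domain (F0={F0:.3g}, F1={F1:.3g})")
    resid = float(np.mean((model(wf, *popt) - rf) ** 2))
    return FitResult(F0=F0, F1=F1, interval=interval, residual=resid)


def mf_params_from_fit(fit: FitResult, triplet: TripletParams,
                       homeo: HomeostasisConfig) -> MFParams:
    """Assemble the mean-field parameter set from a response fit and the
    plasticity configuration."""
    return MFParams(
        F0=fit.F0, F1=fit.F1,
        tau_w=effective_tau_w(triplet),
        eta=triplet.eta, kappa=triplet.kappa,
        tau_bar=homeo.tau_bar, beta=homeo.beta,
        decay_rate=(1.0 / homeo.tau_decay
                    if homeo.variant == "weight_decay" else 0.0),
        tau_scaling=homeo.tau_scaling,
        scaling_exponent=homeo.scaling_exponent,
        w0=triplet.w0,
    )


def calibrate_network(config: NetworkConfig,
                      settle: float = 10.0,
                      measure: float = 15.0,
                      rel_interval: Tuple[float, float] = (0.88, 1.06),
                      n_points: int = 8,
                      seed: Optional[int] = None) -> FitResult:
    """One-call calibration: scan the rate response on a narrow interval
    around the operating weight and fit the linearised response there.

    The interval is asymmetric because the response pole sits a few percent
    above the operating point; beyond it the rate saturates and the
    linearised model no longer applies.
    """
    w_values = config.w_ee * np.linspace(rel_interval[0], rel_interval[1],
                                         n_points)
    w, r, _ = scan_rate_response(config, w_values=w_values, settle=settle,
                                 measure=measure, seed=seed)
    return fit_linear_response(w, r)


def sweep_tau_critical(config: NetworkConfig,
                       triplet: TripletParams,
                       homeo: HomeostasisConfig,
                       tau_bar_grid: Sequence[float],
                       max_duration: float = 300.0,
                       warmup: float = 10.0,
                       upper_bound: float = 30.0,
                       lower_bound: float = 0.1,
                       quiet_window: float = 10.0,
                       neuron_params: NeuronParams = NeuronParams(),
                       dt: float = 1e-4,
                       seed: Optional[int] = None,
                       ) -> Tuple[List[LifetimeResult], TransitionEstimate]:
    """Lifetime of the background state for each rate-detector timescale.

    Runs the plastic network at every ``tau_bar`` on the (ascending) grid
    for up to ``max_duration`` seconds of biological time and classifies the
    outcome; the transition estimate is the midpoint between the last
    stable and first unstable grid point.
    """
    grid = list(tau_bar_grid)
    if sorted(grid) != grid:
        raise ConfigurationError("tau_bar grid must be ascending")
    net = build_network(config, seed=seed)
    results: List[LifetimeResult] = []
    base_seed = seed if seed is not None else config.seed
    for k, tb in enumerate(grid):
        h = HomeostasisConfig(variant=homeo.variant, tau_bar=tb,
                              beta=homeo.beta, tau_decay=homeo.tau_decay,
                              tau_scaling=homeo.tau_scaling,
                              scaling_exponent=homeo.scaling_exponent,
                              apply_period=homeo.apply_period)
        res = simulate(net, neuron_params, duration=max_duration, dt=dt,
                       plasticity=(triplet, h), warmup=warmup,
                       seed=base_seed + 1000 * (k + 1), record_raster=0,
                       rate_window=1.0, stop_above=upper_bound,
                       abort_rate=max(4.0 * upper_bound, 100.0))
        if res.aborted_at is not None:
            lt = LifetimeResult(lifetime=res.aborted_at, outcome="runaway",
                                tau_bar=tb)
        else:
            lt = detect_instability(res.rates.times, res.rates.exc,
                                    lower_bound=lower_bound,
                                    upper_bound=upper_bound,
                                    quiet_window=quiet_window, tau_bar=tb)
            if lt.outcome == "stable" and res.duration < max_duration - 1e-9:
                lt = LifetimeResult(lifetime=res.duration, outcome="runaway",
                                    tau_bar=tb)
        results.append(lt)
    stable = [r.tau_bar for r in results if r.outcome == "stable"]
    unstable = [r.tau_bar for r in results if r.outcome != "stable"]
    if stable and unstable:
        last_stable = max(stable)
        first_unstable = min(u for u in unstable if u > last_stable) \
            if any(u > last_stable for u in unstable) else min(unstable)
        est = TransitionEstimate(value=0.5 * (last_stable + first_unstable),
                                 last_stable=last_stable,
                                 first_unstable=first_unstable, censored=None)
    elif stable:
        est = TransitionEstimate(value=np.inf, last_stable=max(stable),
                                 first_unstable=np.inf, censored="all_stable")
    else:
        est = TransitionEstimate(value=-np.inf, last_stable=-np.inf,
                                 first_unstable=min(unstable),
                                 censored="all_unstable")
    return results, est
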