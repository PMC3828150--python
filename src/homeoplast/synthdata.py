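"""Seeded spike-train generators and brute-force plasticity oracles.

Everything here is a pure function of its arguments and a seed.  The two
oracles (:func:`dense_grid_oracle`, :func:`mc_drift_oracle`) deliberately
share no code with the event-driven plasticity engine they validate: the
dense-grid oracle evaluates the triplet rule on a fixed time grid with
per-step exponential decay factors (an exponential integrator implemented
with :func:`scipy.signal.lfilter`), the Monte-Carlo oracle averages the rule
over freshly drawn Poisson trains with a simple explicit event walk.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal import lfilter

from .params import TripletParams, ConfigurationError

__all__ = [
    "TrainSpec",
    "poisson_trains",
    "regular_train",
    "pairing_train",
    "dense_grid_oracle",
    "mc_drift_oracle",
]


@dataclass(frozen=True)
class TrainSpec:
    """Specification of a synthetic spike train.

    ``kind`` is ``poisson`` (homogeneous), ``regular`` (equidistant) or
    ``paired`` (pre/post pairs with offset ``offset = t_pre - t_post`` in
    seconds).
    """

    rate: float
    duration: float
    kind: str = "poisson"
    offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.rate < 0:
            raise ConfigurationError("rate must be nonnegative")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.kind not in ("poisson", "regular", "paired"):
            raise ConfigurationError(f"unknown train kind {self.kind!r}")


def poisson_trains(spec: TrainSpec, n: int = 1) -> List[np.ndarray]:
    """``n`` independent homogeneous Poisson spike-time arrays.

    Train ``i`` is a deterministic function of ``(spec.seed, i)`` only.
    """
    trains = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, i)))
        if spec.rate == 0:
            trains.append(np.empty(0))
            continue
        expected = spec.rate * spec.duration
        m = int(expected + 5 * np.sqrt(expected + 1) + 10)
        times = np.cumsum(rng.exponential(1.0 / spec.rate, size=m))
        while times[-1] < spec.duration:
            extra = np.cumsum(rng.exponential(1.0 / spec.rate, size=m)) + times[-1]
            times = np.concatenate([times, extra])
        trains.append(times[times < spec.duration])
    return trains


def regular_train(rate: float, duration: float, start: float = 0.0) -> np.ndarray:
    """Equidistant spike times at ``rate`` Hz on ``[start, start+duration)``."""
    if rate <= 0:
        return np.empty(0)
    n = int(np.floor(rate * duration))
    return start + np.arange(n) / rate


def pairing_train(n_pairs: int, pair_rate: float, offset: float,
                  start: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
    """Standard pre/post pairing protocol.

    ``offset = t_pre - t_post``: negative means pre-before-post (the LTP
    direction for pair STDP), positive means post-before-pre is reversed --
    i.e. pre fires ``offset`` seconds after each post spike.  Returns
    ``(pre_times, post_times)``, all times >= ``start``.
    """
    if n_pairs <= 0:
        raise ConfigurationError("n_pairs must be positive")
    if pair_rate <= 0:
        raise ConfigurationError("pair_rate must be positive")
    if abs(offset) >= 1.0 / pair_rate:
        raise ConfigurationError("|offset| must be smaller than the pairing period")
    base = start + max(0.0, -offset)
    post = base + np.arange(n_pairs) / pair_rate
    pre = post + offset
    return pre, post


def _binned(times: np.ndarray, dt: float, n_bins: int) -> np.ndarray:
    s = np.zeros(n_bins)
    if times.size:
        idx = np.round(np.asarray(times, dtype=float) / dt).astype(np.int64)
        if idx.min() < 0 or idx.max() >= n_bins:
            raise ValueError("spike time outside the grid")
        np.add.at(s, idx, 1.0)
    return s


def dense_grid_oracle(pre: np.ndarray, post: np.ndarray, triplet: TripletParams,
                      rbar_clamp: Optional[float] = None,
                      tau_bar: float = 10.0,
                      rbar0: float = 0.0,
                      beta: float = 2.0,
                      dt_fine: float = 1e-6,
                      duration: Optional[float] = None,
                      metaplastic: bool = True) -> float:
    """Reference total weight change of a single synapse on a dense grid.

    Spike times are binned to the grid; all traces are propagated with the
    exact per-step decay factor ``exp(-dt/tau)`` so that the only
    discretisation effect is the binning itself.  Weight bounds are *not*
    applied -- the oracle reports the raw accumulated update.

    With ``rbar_clamp`` the postsynaptic rate estimate is frozen (stationary
    drift measurements); otherwise it is the low-pass filtered postsynaptic
    train (time constant ``tau_bar``) starting from ``rbar0``.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if duration is None:
        duration = max(pre.max(initial=0.0), post.max(initial=0.0)) + dt_fine
    n = int(np.ceil(duration / dt_fine)) + 1
    s_pre = _binned(pre, dt_fine, n)
    s_post = _binned(post, dt_fine, n)

    def filt(s, tau, y0=0.0):
        d = np.exp(-dt_fine / tau)
        # z[k] = d z[k-1] + s[k]: trace value *after* the spikes of bin k
        z, _ = lfilter([1.0], [1.0, -d], s, zi=np.array([d * y0]))
        return z

    def before(z, tau, y0=0.0):
        # trace value at bin k after decay but before the spikes of bin k
        d = np.exp(-dt_fine / tau)
        zb = np.empty_like(z)
        zb[0] = d * y0
        zb[1:] = z[:-1] * d
        return zb

    z_plus_b = before(filt(s_pre, triplet.tau_plus), triplet.tau_plus)
    z_minus_b = before(filt(s_post, triplet.tau_minus), triplet.tau_minus)
    z_slow_b = before(filt(s_post, triplet.tau_y), triplet.tau_y)

    if rbar_clamp is not None:
        rbar_b = np.full(n, float(rbar_clamp))
    else:
        z = filt(s_post / 1.0, tau_bar, y0=rbar0 * tau_bar)
        rbar_b = before(z, tau_bar, y0=rbar0 * tau_bar) / tau_bar

    scale = triplet.eta * triplet.w0
    if metaplastic:
        a2 = triplet.A2_minus_ref * (rbar_b / triplet.kappa) ** beta
    else:
        a2 = np.full(n, triplet.A2_minus_ref)

    # pre spikes depress via the postsynaptic fast trace; post spikes
    # potentiate via the presynaptic fast trace and the slow postsynaptic
    # trace, all evaluated just before the spikes of the bin
    ltd = -scale * np.sum(s_pre * a2 * z_minus_b)
    ltp = scale * triplet.A3_plus * np.sum(s_post * z_plus_b * z_slow_b)
    return float(ltd + ltp)


def mc_drift_oracle(r_pre: float, r_post: float, r_bar: float,
                    triplet: TripletParams, n_reps: int = 100,
                    duration: float = 100.0, seed: int = 0,
                    beta: float = 2.0,
                    metaplastic: bool = True) -> Tuple[float, float]:
    """Monte-Carlo expected weight drift (per second) of the triplet rule on
    independent Poisson pre/post trains with the rate estimate clamped at
    ``r_bar``.

    Returns ``(mean, standard error)``.  The event walk below evaluates the
    exact exponential trace decays between events; it is intentionally
    simple and explicit.
    """
    if n_reps < 2:
        raise ConfigurationError("n_reps must be at least 2")
    scale = triplet.eta * triplet.w0
    if metaplastic:
        a2 = triplet.A2_minus_ref * (r_bar / triplet.kappa) ** beta
    else:
        a2 = triplet.A2_minus_ref
    drifts = np.empty(n_reps)
    for rep in range(n_reps):
        pre = poisson_trains(TrainSpec(r_pre, duration, seed=seed * 100003 + 2 * rep))[0]
        post = poisson_trains(TrainSpec(r_post, duration, seed=seed * 100003 + 2 * rep + 1))[0]
        dw = 0.0
        z_plus = z_minus = z_slow = 0.0
        t = 0.0
        i = j = 0
        while i < pre.size or j < post.size:
            tp = pre[i] if i < pre.size else np.inf
            tq = post[j] if j < post.size else np.inf
            tn = min(tp, tq)
            z_plus *= np.exp(-(tn - t) / triplet.tau_plus)
            z_minus *= np.exp(-(tn - t) / triplet.tau_minus)
            z_slow *= np.exp(-(tn - t) / triplet.tau_y)
            t = tn
            if tp <= tq:
                dw += -scale * a2 * z_minus
                z_plus += 1.0
                i += 1
            else:
                dw += scale * triplet.A3_plus * z_plus * z_slow
                z_minus += 1.0
                z_slow += 1.0
                j += 1
        drifts[rep] = dw / duration
    return float(drifts.mean()), float(drifts.std(ddof=1) / np.sqrt(n_reps))
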