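"""Event-driven triplet STDP with three homeostatic mechanisms.

The rule is the minimal all-to-all triplet model: every presynaptic spike
depresses the synapse in proportion to the fast postsynaptic trace
``z_minus``; every postsynaptic spike potentiates it in proportion to the
fast presynaptic trace ``z_plus`` times the slow postsynaptic trace
``z_slow`` evaluated *just before* the spike.  Updates act additively on the
weight, scaled by ``eta * w0``, and are clipped to ``[w_min, w_max]``.

Homeostasis enters in one of three ways:

* metaplastic LTD -- the depression amplitude slides with the neuron's own
  rate estimate, ``A2_minus(rbar) = A2_minus_ref * (rbar/kappa)**beta``;
* slow weight decay -- the metaplastic rule plus multiplicative decay of all
  weights with time constant ``tau_decay``;
* synaptic scaling -- fixed LTD amplitude, afferent weights multiplicatively
  scaled towards the target rate ``kappa``.

Decay and scaling are applied in periodic batches (:func:`apply_weight_decay`,
:func:`apply_synaptic_scaling`), which approximates the continuous process
to high accuracy when the period is much shorter than their time constants.

This module is the exact, event-driven reference implementation used for
isolated synapses and plasticity protocols; the network simulator applies
the same rule inside its compiled update loop (the two are cross-validated
against each other and against the dense-grid oracle in the test suite).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .params import TripletParams, HomeostasisConfig, ConfigurationError

__all__ = [
    "SynapticTraces",
    "TripletSynapse",
    "update_rate_estimate",
    "ltd_amplitude",
    "process_spike_event",
    "apply_weight_decay",
    "apply_synaptic_scaling",
]


@dataclass
class SynapticTraces:
    """Exponentially decaying spike traces of a single neuron.

    ``r_bar`` is the homeostatic rate estimate (the spike train low-pass
    filtered with time constant ``tau_bar``: decays between spikes, jumps by
    ``1/tau_bar`` at each spike).
    """

    z_plus: float = 0.0
    z_minus: float = 0.0
    z_slow: float = 0.0
    r_bar: float = 0.0
    t: float = 0.0

    def decay_to(self, t: float, triplet: TripletParams, tau_bar: float) -> None:
        if t < self.t:
            raise ValueError(f"time running backwards: {t} < {self.t}")
        dt = t - self.t
        if dt > 0:
            self.z_plus *= np.exp(-dt / triplet.tau_plus)
            self.z_minus *= np.exp(-dt / triplet.tau_minus)
            self.z_slow *= np.exp(-dt / triplet.tau_y)
            self.r_bar *= np.exp(-dt / tau_bar)
            self.t = t

    def on_spike(self, tau_bar: float) -> None:
        """Increment all own traces after the spike has been processed."""
        self.z_plus += 1.0
        self.z_minus += 1.0
        self.z_slow += 1.0
        self.r_bar += 1.0 / tau_bar


def update_rate_estimate(traces: SynapticTraces, t: float, spike: bool,
                         triplet: TripletParams, tau_bar: float) -> float:
    """Advance the rate estimate of ``traces`` to time ``t``.

    Returns the updated ``r_bar`` (Hz).  With ``spike=True`` the estimate is
    incremented by ``1/tau_bar`` after the decay.
    """
    traces.decay_to(t, triplet, tau_bar)
    if spike:
        traces.r_bar += 1.0 / tau_bar
    return traces.r_bar


def ltd_amplitude(r_bar: float, triplet: TripletParams, beta: float = 2.0) -> float:
    """Homeostatically modulated depression amplitude.

    Power law ``A2_minus_ref * (r_bar / kappa)**beta`` normalised such that
    at ``r_bar = kappa`` the expected Poisson drift at pre = post = kappa
    vanishes.  A silent neuron (``r_bar = 0``) experiences no LTD.
    """
    if r_bar < 0:
        raise ValueError("r_bar must be nonnegative")
    return triplet.A2_minus_ref * (r_bar / triplet.kappa) ** beta


@dataclass
class TripletSynapse:
    """A single plastic synapse between one pre- and one postsynaptic neuron.

    Used for isolated plasticity protocols (pairing, priming) and as the
    reference implementation in oracle-equivalence tests.  Set
    ``metaplastic=False`` for the fixed-LTD rule used with synaptic scaling.
    """

    triplet: TripletParams
    tau_bar: float = 10.0
    beta: float = 2.0
    metaplastic: bool = True
    clip: bool = True
    w: float = field(default=None)  # type: ignore[assignment]
    pre: SynapticTraces = field(default_factory=SynapticTraces)
    post: SynapticTraces = field(default_factory=SynapticTraces)

    def __post_init__(self):
        if self.w is None:
            self.w = self.triplet.w0

    def _clip(self) -> None:
        if self.clip:
            self.w = min(max(self.w, self.triplet.w_min), self.triplet.w_max)

    def process_spike_event(self, event: str, t: float) -> float:
        """Apply one pre- or postsynaptic spike at time ``t``.

        Traces are decayed to ``t`` first; the update uses the trace values
        *before* the spiking neuron's own increments (use-then-increment).
        Returns the applied weight change.
        """
        p = self.triplet
        self.pre.decay_to(t, p, self.tau_bar)
        self.post.decay_to(t, p, self.tau_bar)
        scale = p.eta * p.w0
        if event == "pre":
            if self.metaplastic:
                a2 = ltd_amplitude(self.post.r_bar, p, self.beta)
            else:
                a2 = p.A2_minus_ref
            dw = -scale * a2 * self.post.z_minus
            self.pre.on_spike(self.tau_bar)
        elif event == "post":
            dw = scale * p.A3_plus * self.pre.z_plus * self.post.z_slow
            self.post.on_spike(self.tau_bar)
        else:
            raise ValueError(f"unknown event type {event!r}")
        w_old = self.w
        self.w += dw
        self._clip()
        return self.w - w_old

    def run(self, pre_times, post_times) -> float:
        """Process two merged spike trains; returns the net weight change.

        Simultaneous pre/post events are processed with the pre spike first,
        matching the network kernel's convention.
        """
        pre_times = np.asarray(pre_times, dtype=float)
        post_times = np.asarray(post_times, dtype=float)
        w_start = self.w
        i = j = 0
        while i < pre_times.size or j < post_times.size:
            tp = pre_times[i] if i < pre_times.size else np.inf
            tq = post_times[j] if j < post_times.size else np.inf
            if tp <= tq:
                self.process_spike_event("pre", tp)
                i += 1
            else:
                self.process_spike_event("post", tq)
                j += 1
        return self.w - w_start


def process_spike_event(synapse: TripletSynapse, event: str, t: float) -> float:
    """Functional form of :meth:`TripletSynapse.process_spike_event`."""
    return synapse.process_spike_event(event, t)


def apply_weight_decay(weights: sp.spmatrix, elapsed: float,
                       tau_decay: float) -> sp.spmatrix:
    """Multiply all plastic weights by ``exp(-elapsed / tau_decay)`` in place.

    Structural zeros (absent synapses) are untouched.  ``tau_decay = inf``
    disables the decay and recovers the base model.
    """
    if elapsed < 0:
        raise ValueError("elapsed must be nonnegative")
    if not np.isinf(tau_decay):
        weights.data *= np.exp(-elapsed / tau_decay)
    return weights


def apply_synaptic_scaling(weights: sp.csr_matrix, r_bar: np.ndarray,
                           elapsed: float, tau_scaling: float, kappa: float,
                           exponent: float = 4.0,
                           w_min: float = 0.0,
                           w_max: float = np.inf) -> sp.csr_matrix:
    """Multiplicatively scale each neuron's afferent weights towards the
    target rate, in place.

    Integrating ``dw/dt = w * (1 - (rbar_i/kappa)**exponent) / tau_scaling``
    over ``elapsed`` seconds with the rate estimate frozen gives the factor
    ``exp(elapsed/tau_scaling * (1 - (rbar_i/kappa)**exponent))`` for every
    afferent (column ``i``) weight: weights grow when the postsynaptic
    neuron fires below target and shrink above it.  Results are clipped to
    ``[w_min, w_max]``.
    """
    if elapsed < 0:
        raise ValueError("elapsed must be nonnegative")
    weights = weights.tocsr() if not sp.issparse(weights) else weights
    n_post = weights.shape[1]
    r_bar = np.asarray(r_bar, dtype=float)
    if r_bar.shape != (n_post,) or not np.all(np.isfinite(r_bar)):
        raise ValueError("r_bar must provide one finite value per postsynaptic neuron")
    log_factor = (elapsed / tau_scaling) * (1.0 - (r_bar / kappa) ** exponent)
    if isinstance(weights, sp.csr_matrix):
        weights.data *= np.exp(log_factor)[weights.indices]
    else:
        raise TypeError("weights must be a CSR matrix (pre x post)")
    np.clip(weights.data, w_min, w_max, out=weights.data)
    return weights
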