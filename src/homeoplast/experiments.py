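"""Config-driven drivers for the study's figure-level experiments at desk
scale: stability runs under ongoing plasticity, weight-distribution
diagnostics, and the postsynaptic-priming plasticity protocol.

Full-scale runs over 24 h of biological time are out of desk reach; the
presets therefore use the down-scaled network with an inflated relative
learning rate (which shortens every plasticity timescale proportionally)
and declare both in their metadata.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .params import (NetworkConfig, NeuronParams, TripletParams,
                     HomeostasisConfig, ConfigurationError, scaled_network)
from .plasticity import TripletSynapse
from .spikenet import (build_network, simulate, detect_instability,
                       LifetimeResult, SimResult)
from .synthdata import pairing_train, regular_train

__all__ = [
    "ProtocolSpec",
    "PrimingResult",
    "StabilityExperiment",
    "run_stability_experiment",
    "weight_distribution_summary",
    "run_priming_protocol",
    "PRESETS",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Pairing protocol with optional postsynaptic priming.

    ``offset`` is the pairing offset in the Delta t = t_post - t_pre
    convention: -10 ms is the post-before-pre (LTD) protocol, +10 ms the
    pre-before-post (LTP) protocol.  Priming: regular postsynaptic firing at
    ``priming_frequency`` for ``priming_duration``, terminated by
    ``priming_gap`` seconds of silence (to let the fast triplet traces decay)
    before the pairing starts.
    """

    n_pairs: int = 75
    pair_rate: float = 5.0
    offset: float = -10e-3
    priming_duration: float = 100.0
    priming_frequency: float = 3.0
    priming_gap: float = 1.0

    def __post_init__(self):
        if self.n_pairs <= 0:
            raise ConfigurationError("n_pairs must be positive")
        if abs(self.offset) >= 1.0 / self.pair_rate:
            raise ConfigurationError("|offset| must be below the pairing period")
        if self.priming_gap < 0:
            raise ConfigurationError("priming_gap must be nonnegative")


@dataclass
class PrimingResult:
    dw_quiet: float
    dw_primed: float
    relative_difference: float
    trace_times: np.ndarray    # times of the pairing events (primed run)
    trace_w: np.ndarray        # weight after each event (primed run)
    r_bar_at_onset: float      # rate estimate at the start of the pairing


def _run_pairing(spec: ProtocolSpec, triplet: TripletParams, tau_bar: float,
                 beta: float, primed: bool) -> Tuple[float, np.ndarray,
                                                     np.ndarray, float]:
    syn = TripletSynapse(triplet, tau_bar=tau_bar, beta=beta)
    t0 = 0.0
    if primed:
        for t in regular_train(spec.priming_frequency, spec.priming_duration):
            syn.process_spike_event("post", t)
        t0 = spec.priming_duration + spec.priming_gap
    pre, post = pairing_train(spec.n_pairs, spec.pair_rate, -spec.offset,
                              start=t0)
    # rate estimate at pairing onset (convention: the cell is quiescent
    # before the experiment, so r_bar starts at zero)
    syn.pre.decay_to(t0, triplet, tau_bar)
    syn.post.decay_to(t0, triplet, tau_bar)
    rbar0 = syn.post.r_bar
    w_start = syn.w
    events = sorted([(t, "pre") for t in pre] + [(t, "post") for t in post])
    times = np.array([t for t, _ in events])
    w_trace = np.empty(times.size)
    for k, (t, kind) in enumerate(events):
        syn.process_spike_event(kind, t)
        w_trace[k] = syn.w
    return syn.w - w_start, times, w_trace, rbar0


def run_priming_protocol(spec: ProtocolSpec,
                         triplet: Optional[TripletParams] = None,
                         tau_bar: float = 60.0,
                         beta: float = 2.0) -> PrimingResult:
    """Compare a pairing protocol on a quiescent cell against the same
    protocol after postsynaptic priming.

    With the metaplastic rule the depression amplitude follows the rate
    estimate, so LTD changes dramatically with priming while LTP (which does
    not depend on the estimate) is unaffected.  Returns the weight changes
    and their relative difference ``(dw_primed - dw_quiet)/|dw_quiet|``.
    """
    if triplet is None:
        triplet = TripletParams(eta=1.0)
    dw_q, _, _, _ = _run_pairing(spec, triplet, tau_bar, beta, primed=False)
    dw_p, times, w_trace, rbar0 = _run_pairing(spec, triplet, tau_bar, beta,
                                               primed=True)
    denom = abs(dw_q) if dw_q != 0 else np.finfo(float).tiny
    return PrimingResult(dw_quiet=dw_q, dw_primed=dw_p,
                         relative_difference=(dw_p - dw_q) / denom,
                         trace_times=times, trace_w=w_trace,
                         r_bar_at_onset=rbar0)


@dataclass
class StabilityExperiment:
    lifetime: LifetimeResult
    sim: SimResult
    config: NetworkConfig
    triplet: TripletParams
    homeostasis: HomeostasisConfig
    metadata: Dict


def run_stability_experiment(config: NetworkConfig,
                             triplet: TripletParams,
                             homeo: HomeostasisConfig,
                             duration: float,
                             warmup: float = 10.0,
                             seed: Optional[int] = None,
                             snapshot_interval: Optional[float] = 60.0,
                             upper_bound: float = 30.0,
                             lower_bound: float = 0.1,
                             quiet_window: float = 10.0,
                             neuron_params: NeuronParams = NeuronParams(),
                             dt: float = 1e-4,
                             record_raster: Tuple[int, int] = (500, 0),
                             ) -> StabilityExperiment:
    """Full pipeline run: plastic network with periodic monitoring, rate
    trace, weight snapshots and lifetime classification."""
    net = build_network(config, seed=seed)
    res = simulate(net, neuron_params, duration=duration, dt=dt,
                   plasticity=(triplet, homeo), warmup=warmup, seed=seed,
                   record_raster=record_raster, rate_window=1.0,
                   snapshot_interval=snapshot_interval,
                   stop_above=upper_bound, abort_rate=max(4.0 * upper_bound, 100.0))
    if res.aborted_at is not None:
        lt = LifetimeResult(lifetime=res.aborted_at, outcome="runaway",
                            tau_bar=homeo.tau_bar)
    else:
        lt = detect_instability(res.rates.times, res.rates.exc,
                                lower_bound=lower_bound,
                                upper_bound=upper_bound,
                                quiet_window=quiet_window,
                                tau_bar=homeo.tau_bar)
        if lt.outcome == "stable" and res.duration < duration - 1e-9:
            lt = LifetimeResult(lifetime=res.duration, outcome="runaway",
                                tau_bar=homeo.tau_bar)
    meta = {"seed": seed if seed is not None else config.seed,
            "eta": triplet.eta, "variant": homeo.variant,
            "tau_bar": homeo.tau_bar, "scaled_down": config.N_exc < 20000,
            "note": ("down-scaled network with inflated learning rate; "
                     "plasticity timescales shrink proportionally to 1/eta"
                     if config.N_exc < 20000 else "full-scale configuration")}
    return StabilityExperiment(lifetime=lt, sim=res, config=config,
                               triplet=triplet, homeostasis=homeo,
                               metadata=meta)


@dataclass
class WeightDistributionSummary:
    times: np.ndarray
    edges: np.ndarray
    histograms: np.ndarray      # (n_snapshots, n_bins), each normalised
    bimodality: np.ndarray      # valley-to-peak score per snapshot

    def is_bimodal(self, threshold: float = 2.0) -> np.ndarray:
        return self.bimodality > threshold


def weight_distribution_summary(snapshots: Sequence[Tuple[float, np.ndarray]],
                                w_min: float = 0.0, w_max: float = 1.0,
                                bins: int = 50) -> WeightDistributionSummary:
    """Histogram series over ``[w_min, w_max]`` plus a bimodality score.

    The score is the smaller of the two boundary-bin masses divided by the
    deepest point of the interior valley (middle 60 % of the range), with
    the valley floored at ``1/(10 bins)`` to keep the ratio finite.  A
    purely additive rule drives weights to both bounds (score >> 1); decay
    or scaling keeps the distribution unimodal away from the bounds
    (score ~ 0).
    """
    if not snapshots:
        raise ConfigurationError("need at least one weight snapshot")
    edges = np.linspace(w_min, w_max, bins + 1)
    hists = []
    scores = []
    lo = max(int(bins * 0.2), 1)
    hi = bins - lo
    floor = 1.0 / (10.0 * bins)
    for _, w in snapshots:
        h, _ = np.histogram(w, bins=edges, density=False)
        h = h / max(h.sum(), 1)
        valley = h[lo:hi].min()
        scores.append(min(h[0], h[-1]) / max(valley, floor))
        hists.append(h)
    return WeightDistributionSummary(
        times=np.array([t for t, _ in snapshots]),
        edges=edges, histograms=np.array(hists),
        bimodality=np.array(scores))


def _desk_config(seed: int) -> NetworkConfig:
    return scaled_network(5, seed=seed)


def _desk_triplet(eta: float = 50.0) -> TripletParams:
    return TripletParams(eta=eta)


PRESETS: Dict[str, Dict] = {
    # stability of the background state under the metaplastic rule
    "stability": dict(kind="stability", variant="metaplastic_ltd",
                 tau_bars=(2.0, 10.0, 60.0), duration=120.0, eta=50.0),
    # lifetimes across the rate-detector timescale
    "lifetime-sweep": dict(kind="sweep", variant="metaplastic_ltd",
                 tau_bars=(1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0),
                 duration=120.0, eta=50.0),
    # slow weight decay
    "weight-decay": dict(kind="stability", variant="weight_decay",
                 tau_bars=(2.0, 10.0), duration=120.0, eta=50.0,
                 tau_decay=600.0),
    # synaptic scaling
    "synaptic-scaling": dict(kind="stability", variant="synaptic_scaling",
                 tau_bars=(2.0, 10.0), duration=120.0, eta=50.0,
                 tau_scaling=60.0),
    # postsynaptic priming protocol (isolated pair, biological eta)
    "priming": dict(kind="priming",
                 frequencies=(0.5, 1.0, 2.0, 3.0, 4.0, 5.0),
                 durations=(5.0, 10.0, 20.0, 40.0, 80.0, 160.0)),
}
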