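"""Conductance-based leaky integrate-and-fire network with adaptive
thresholds, sparse random connectivity and external Poisson drive.

The model: membrane voltages integrate leak, excitatory (AMPA + slow NMDA
mixture) and inhibitory (GABA) conductances; a spike is triggered when the
voltage crosses a dynamic threshold which jumps by ``delta_theta`` after
each spike and relaxes back (relative refractoriness).  20 000 excitatory
and 5 000 inhibitory neurons are randomly connected at 5 %; every
excitatory neuron additionally receives input from 2 500 external Poisson
sources at 2 Hz connected at 5 %.  With the reference weights the network
sits in the asynchronous irregular balanced state at ~3 Hz.

Integration is synchronous forward Euler at 0.1 ms; within a step the order
is (1) decay, (2) voltage integration, (3) threshold test/reset, (4)
propagation of this step's spikes (effective next step).  No transmission
delays.  Runs are bit-reproducible given the master seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .params import (NeuronParams, NetworkConfig, TripletParams,
                     HomeostasisConfig, ConfigurationError)

__all__ = [
    "Network",
    "SpikeRaster",
    "RateTrace",
    "SimResult",
    "LifetimeResult",
    "NumericalBlowupError",
    "build_network",
    "simulate",
    "population_rate",
    "isi_statistics",
    "detect_instability",
    "epsp_probe",
]


class NumericalBlowupError(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclass
class Network:
    """Sparse random network: four recurrent blocks plus the external block.

    All blocks are CSR matrices indexed (presynaptic, postsynaptic) with
    population-local indices; ``ee`` is the plastic block (its structural
    zeros are absent synapses and never become present).
    """

    config: NetworkConfig
    ee: sp.csr_matrix
    ei: sp.csr_matrix
    ie: sp.csr_matrix
    ii: sp.csr_matrix
    ext: sp.csr_matrix

    @property
    def n_exc(self) -> int:
        return self.config.N_exc

    @property
    def n_inh(self) -> int:
        return self.config.N_inh

    def ee_in_degrees(self) -> np.ndarray:
        """Number of recurrent excitatory synapses onto each E neuron."""
        return np.asarray((self.ee != 0).sum(axis=0)).ravel()

    def copy(self) -> "Network":
        return Network(self.config, self.ee.copy(), self.ei.copy(),
                       self.ie.copy(), self.ii.copy(), self.ext.copy())


def _random_block(rng: np.random.Generator, n_pre: int, n_post: int,
                  p: float, w: float, no_self: bool,
                  chunk: int = 512) -> sp.csr_matrix:
    """Bernoulli(p) adjacency with constant weight w, generated in row
    chunks to bound memory."""
    counts: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    for start in range(0, n_pre, chunk):
        stop = min(start + chunk, n_pre)
        if p > 0:
            u = rng.random((stop - start, n_post), dtype=np.float32)
            mask = u < p
            if no_self and n_pre == n_post:
                mask[np.arange(stop - start), np.arange(start, stop)] = False
            rr, cc = np.nonzero(mask)
            counts.append(np.bincount(rr, minlength=stop - start))
            cols.append(cc.astype(np.int32))
        else:
            counts.append(np.zeros(stop - start, dtype=np.int64))
    row_counts = np.concatenate(counts)
    indptr = np.concatenate([[0], np.cumsum(row_counts)]).astype(np.int64)
    indices = np.concatenate(cols) if cols else np.empty(0, dtype=np.int32)
    data = np.full(indices.shape[0], w, dtype=np.float64)
    return sp.csr_matrix((data, indices, indptr), shape=(n_pre, n_post))


def build_network(config: NetworkConfig, seed: Optional[int] = None) -> Network:
    """Draw the sparse random connectivity.

    Each ordered (pre, post) pair is connected independently with
    probability ``p_conn`` (no self-connections within a population);
    external sources project to excitatory neurons with probability
    ``p_ext``.  Deterministic given the seed (``config.seed`` if not
    supplied).
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(ord("c"),))
    rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
    c = config
    ee = _random_block(rngs[0], c.N_exc, c.N_exc, c.p_conn, c.w_ee, True)
    ei = _random_block(rngs[1], c.N_exc, c.N_inh, c.p_conn, c.w_ei, False)
    ie = _random_block(rngs[2], c.N_inh, c.N_exc, c.p_conn, c.w_ie, False)
    ii = _random_block(rngs[3], c.N_inh, c.N_inh, c.p_conn, c.w_ii, True)
    ext = _random_block(rngs[4], c.N_ext, c.N_exc, c.p_ext, c.w_ext, False)
    return Network(config=c, ee=ee, ei=ei, ie=ie, ii=ii, ext=ext)


@dataclass
class SpikeRaster:
    """Spike events ``(time, neuron_id)``, time-ordered.

    Excitatory neurons have global ids ``0 .. n_exc_total-1``, inhibitory
    neurons ``n_exc_total .. n_exc_total+n_inh_total-1``.  Only the first
    ``n_exc_recorded`` / ``n_inh_recorded`` neurons of each population are
    recorded (rate normalisation uses the recorded counts).
    """

    times: np.ndarray
    ids: np.ndarray
    duration: float
    n_exc_total: int
    n_inh_total: int
    n_exc_recorded: int
    n_inh_recorded: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.times.size and (np.any(np.diff(self.times) < 0)
                                or self.times[0] < 0
                                or self.times[-1] > self.duration + 1e-9):
            raise ValueError("spike times must be nondecreasing within [0, duration]")

    @property
    def events(self):
        return zip(self.times, self.ids)

    def select(self, population: str) -> Tuple[np.ndarray, np.ndarray, int]:
        """(times, ids, recorded population size) of one population."""
        if population == "exc":
            m = self.ids < self.n_exc_total
            return self.times[m], self.ids[m], self.n_exc_recorded
        if population == "inh":
            m = self.ids >= self.n_exc_total
            return self.times[m], self.ids[m], self.n_inh_recorded
        if population == "all":
            return self.times, self.ids, self.n_exc_recorded + self.n_inh_recorded
        raise ValueError(f"unknown population {population!r}")


@dataclass
class RateTrace:
    """Windowed population firing rates (Hz)."""

    times: np.ndarray        # right edges of the windows (s)
    exc: np.ndarray
    inh: np.ndarray
    window: float


@dataclass
class LifetimeResult:
    """Outcome of a stability run: how long the background state survived."""

    lifetime: float
    outcome: str  # stable | runaway | silent
    tau_bar: Optional[float] = None


@dataclass
class SimResult:
    raster: SpikeRaster
    rates: RateTrace
    weight_snapshots: List[Tuple[float, np.ndarray]]
    final_weights: Optional[np.ndarray]
    r_bar: Optional[np.ndarray]
    duration: float
    dt: float
    seed: int
    aborted_at: Optional[float] = None
    final_state: Optional[dict] = None


def _as_int32(a):
    return np.ascontiguousarray(a, dtype=np.int32)


def _slice_schedule(steps, src, offset, n_steps):
    lo = np.searchsorted(steps, offset, side="left")
    hi = np.searchsorted(steps, offset + n_steps, side="left")
    return (steps[lo:hi] - offset, src[lo:hi], np.zeros(1, dtype=np.int64))


def simulate(network: Network,
             neuron_params: NeuronParams = NeuronParams(),
             duration: float = 10.0,
             dt: float = 1e-4,
             plasticity: Optional[Tuple[TripletParams, HomeostasisConfig]] = None,
             seed: Optional[int] = None,
             warmup: float = 0.0,
             record_raster: Union[int, Tuple[int, int]] = (1000, 0),
             rate_window: float = 1.0,
             snapshot_interval: Optional[float] = None,
             stop_above: Optional[float] = None,
             abort_rate: Optional[float] = None,
             abort_grace: float = 1.0,
             chunk: float = 1.0,
             init: str = "balanced",
             init_rates: Tuple[float, float] = (3.0, 6.0),
             ext_schedule: Optional[Tuple[np.ndarray, np.ndarray]] = None,
             inplace_weights: bool = False) -> SimResult:
    """Run the network for ``warmup + duration`` seconds of biological time.

    During the warmup the plasticity traces and rate estimates evolve but no
    weight update is carried out; afterwards plasticity (if any) is on.  The
    rate trace covers the plastic period only; raster times are relative to
    the end of the warmup.

    ``record_raster`` selects how many excitatory/inhibitory neurons enter
    the raster.  ``stop_above`` stops the run early once the windowed
    excitatory rate exceeds the given value; ``abort_rate`` additionally
    bails out mid-chunk once the rate over a 50 ms sliding window exceeds it
    (armed after ``abort_grace`` seconds so the initialisation transient is
    exempt) -- both are runaway guards for lifetime sweeps.  Weight snapshots copy the plastic EE weights every
    ``snapshot_interval`` seconds.  Unless ``inplace_weights`` the
    network's weights are left untouched and the evolved weights are
    returned in ``final_weights``.
    """
    if dt <= 0 or duration <= 0:
        raise ConfigurationError("dt and duration must be positive")
    cfg = network.config
    npar = neuron_params
    NE, NI = cfg.N_exc, cfg.N_inh
    N = NE + NI
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(ord("s"),))
    init_ss, kern_ss = ss.spawn(2)
    rng = np.random.default_rng(init_ss)

    V = rng.uniform(npar.E_rest, npar.theta_rest, size=N)
    theta = np.full(N, npar.theta_rest)
    g_a = np.zeros(N)
    g_n = np.zeros(N)
    g_g = np.zeros(N)
    if init == "balanced":
        # start at the mean conductances of the target operating point so
        # the network settles into the balanced state without passing
        # through a synchronous ignition transient
        nu_e, nu_i = init_rates
        mean_w_ee = network.ee.data.mean() if network.ee.nnz else 0.0
        ga_e = (cfg.N_exc * cfg.p_conn * nu_e * mean_w_ee
                + cfg.N_ext * cfg.p_ext * cfg.ext_rate * cfg.w_ext) * npar.tau_ampa
        gg_e = cfg.N_inh * cfg.p_conn * nu_i * cfg.w_ie * npar.tau_gaba
        ga_i = cfg.N_exc * cfg.p_conn * nu_e * cfg.w_ei * npar.tau_ampa
        gg_i = cfg.N_inh * cfg.p_conn * nu_i * cfg.w_ii * npar.tau_gaba
        g_a[:NE] = ga_e
        g_n[:NE] = ga_e
        g_g[:NE] = gg_e
        g_a[NE:] = ga_i
        g_n[NE:] = ga_i
        g_g[NE:] = gg_i
    elif init != "rest":
        raise ConfigurationError(f"unknown init mode {init!r}")

    ee = network.ee
    ee_w = ee.data if inplace_weights else ee.data.copy()
    ee_ptr, ee_idx = ee.indptr.astype(np.int64), _as_int32(ee.indices)
    ei_ptr, ei_idx = network.ei.indptr.astype(np.int64), _as_int32(network.ei.indices)
    ie_ptr, ie_idx = network.ie.indptr.astype(np.int64), _as_int32(network.ie.indices)
    ii_ptr, ii_idx = network.ii.indptr.astype(np.int64), _as_int32(network.ii.indices)
    ext_ptr, ext_idx = network.ext.indptr.astype(np.int64), _as_int32(network.ext.indices)
    ei_w, ie_w, ii_w, ext_w = (network.ei.data, network.ie.data,
                               network.ii.data, network.ext.data)

    plastic_on = plasticity is not None
    if plastic_on:
        triplet, homeo = plasticity
        metaplastic = homeo.variant in ("metaplastic_ltd", "weight_decay")
        # CSC view of the EE block whose data points into ee_w
        tmp = sp.csr_matrix((np.arange(ee.nnz, dtype=np.int64),
                             ee.indices, ee.indptr), shape=ee.shape).tocsc()
        ee_cptr = tmp.indptr.astype(np.int64)
        ee_cpre = _as_int32(tmp.indices)
        ee_cmap = tmp.data.astype(np.int64)
        zp = np.zeros(NE)
        zm = np.zeros(NE)
        zs = np.zeros(NE)
        rbar = np.full(NE, triplet.kappa)
        f_zp = np.exp(-dt / triplet.tau_plus)
        f_zm = np.exp(-dt / triplet.tau_minus)
        f_zs = np.exp(-dt / triplet.tau_y)
        f_rbar = np.exp(-dt / homeo.tau_bar)
        eta_w0 = triplet.eta * triplet.w0
        plast_args = (ee_cptr, ee_cpre, ee_cmap, zp, zm, zs, rbar,
                      f_zp, f_zm, f_zs, f_rbar,
                      eta_w0 * triplet.A3_plus, eta_w0 * triplet.A2_minus_ref,
                      1.0 / triplet.kappa, homeo.beta, 1.0 / homeo.tau_bar,
                      triplet.w_min, triplet.w_max)
        chunk = min(chunk, homeo.apply_period)
    else:
        triplet = homeo = None
        metaplastic = False
        empty64 = np.zeros(1, dtype=np.int64)
        empty32 = np.zeros(1, dtype=np.int32)
        zp = zm = zs = rbar = np.zeros(1)
        plast_args = (empty64, empty32, empty64, zp, zm, zs, rbar,
                      1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 1.0, 2.0, 1.0, 0.0, 1.0)

    if isinstance(record_raster, int):
        rec_ne, rec_ni = record_raster, 0
    else:
        rec_ne, rec_ni = record_raster
    rec_ne = min(rec_ne, NE)
    rec_ni = min(rec_ni, NI)

    if ext_schedule is not None:
        # prescribed external spikes (time since simulation start, source id)
        ext_lam = -1.0
        sched_t, sched_id = ext_schedule
        order = np.argsort(sched_t, kind="stable")
        sched_all_steps = np.round(np.asarray(sched_t, dtype=float)[order]
                                   / dt).astype(np.int64)
        sched_all_src = np.asarray(sched_id, dtype=np.int32)[order]
    else:
        ext_lam = cfg.N_ext * cfg.ext_rate * dt
        sched_all_steps = np.empty(0, dtype=np.int64)
        sched_all_src = np.empty(0, dtype=np.int32)

    const_args = (
        NE, NI,
        1.0 - dt / npar.tau_ampa, 1.0 - dt / npar.tau_gaba,
        dt / npar.tau_nmda, dt / npar.tau_theta,
        npar.theta_rest, npar.delta_theta,
        dt / npar.tau_mem_exc, dt / npar.tau_mem_inh,
        npar.E_rest, npar.E_exc_rev, npar.E_inh_rev, npar.alpha_nmda,
    )
    state_args = (V, theta, g_a, g_n, g_g)
    conn_args = (ee_ptr, ee_idx, ee_w, ei_ptr, ei_idx, ei_w,
                 ie_ptr, ie_idx, ie_w, ii_ptr, ii_idx, ii_w,
                 cfg.N_ext, ext_lam, ext_ptr, ext_idx, ext_w)

    spike_buf = np.empty(N, dtype=np.int64)
    kern_rng = np.random.default_rng(kern_ss)

    total = warmup + duration
    n_chunks = int(np.ceil(total / chunk - 1e-12)) + 2
    chunk_seeds = kern_rng.integers(0, 2 ** 31 - 1, size=n_chunks)

    rec_times: List[np.ndarray] = []
    rec_ids: List[np.ndarray] = []
    counts_e: List[np.ndarray] = []
    counts_i: List[np.ndarray] = []
    snapshots: List[Tuple[float, np.ndarray]] = []
    dropped = 0
    aborted = False
    last_rate = 10.0
    t_bio = 0.0          # time since simulation start
    step_offset = 0
    next_snapshot = 0.0
    stopped_at = None

    for ci in range(n_chunks):
        in_warmup = t_bio < warmup - 1e-12
        boundary = warmup if in_warmup else total  # never straddle the warmup end
        this_chunk = min(chunk, boundary - t_bio)
        n_steps = int(round(this_chunk / dt))
        if n_steps == 0:
            break
        ecount = np.zeros(n_steps, dtype=np.int32)
        icount = np.zeros(n_steps, dtype=np.int32)
        recording = (rec_ne + rec_ni) > 0 and not in_warmup
        cap = int((rec_ne + rec_ni) * this_chunk * max(100.0, 5 * last_rate)) + 1024 \
            if recording else 1
        rec_t = np.empty(cap)
        rec_id = np.empty(cap, dtype=np.int32)
        rec_state = np.zeros(3, dtype=np.int64)
        t0 = t_bio - warmup  # raster clock starts at the end of the warmup

        _kernels.run_chunk(n_steps, dt, int(chunk_seeds[ci]),
                           *const_args, *state_args, *conn_args,
                           plastic_on, plastic_on and not in_warmup, metaplastic,
                           *plast_args,
                           ecount, icount,
                           rec_ne if recording else 0,
                           rec_ni if recording else 0,
                           rec_t, rec_id, rec_state, t0, spike_buf,
                           int(abort_rate * NE * 0.05)
                           if abort_rate and t_bio >= abort_grace else 0,
                           max(int(round(0.05 / dt)), 1),
                           *_slice_schedule(sched_all_steps, sched_all_src,
                                            step_offset, n_steps))
        step_offset += n_steps

        aborted = rec_state[2] >= 0
        if aborted:
            n_done = int(rec_state[2]) + 1
            ecount = ecount[:n_done]
            icount = icount[:n_done]
            this_chunk = n_done * dt
        if not np.all(np.isfinite(V)):
            raise NumericalBlowupError(
                f"non-finite membrane voltage near t = {t_bio + this_chunk:.3f} s "
                f"(voltage-integration step)")
        t_bio += this_chunk
        if recording:
            npos = int(rec_state[0])
            rec_times.append(rec_t[:npos].copy())
            rec_ids.append(rec_id[:npos].astype(np.int64))
            dropped += int(rec_state[1])
        if not in_warmup:
            counts_e.append(ecount)
            counts_i.append(icount)
        chunk_rate = ecount.sum() / (this_chunk * NE)
        last_rate = max(chunk_rate, 1.0)

        if plastic_on and not in_warmup:
            t_plastic = t_bio - warmup
            if homeo.variant == "weight_decay":
                ee_w *= np.exp(-this_chunk / homeo.tau_decay)
                np.clip(ee_w, triplet.w_min, triplet.w_max, out=ee_w)
            elif homeo.variant == "synaptic_scaling":
                logf = (this_chunk / homeo.tau_scaling) * (
                    1.0 - (rbar / triplet.kappa) ** homeo.scaling_exponent)
                ee_w *= np.exp(logf)[ee_idx]
                np.clip(ee_w, triplet.w_min, triplet.w_max, out=ee_w)
            if snapshot_interval is not None and t_plastic >= next_snapshot - 1e-12:
                snapshots.append((t_plastic, ee_w.copy()))
                next_snapshot += snapshot_interval
        if aborted:
            stopped_at = t_bio - warmup
            break
        if stop_above is not None and not in_warmup and chunk_rate > stop_above:
            stopped_at = t_bio - warmup
            break

    if dropped:
        warnings.warn(f"raster truncated: {dropped} spikes dropped", RuntimeWarning)

    sim_duration = (t_bio - warmup) if t_bio > warmup else 0.0
    times = np.concatenate(rec_times) if rec_times else np.empty(0)
    ids = np.concatenate(rec_ids) if rec_ids else np.empty(0, dtype=np.int64)
    raster = SpikeRaster(times=times, ids=ids, duration=max(sim_duration, dt),
                         n_exc_total=NE, n_inh_total=NI,
                         n_exc_recorded=rec_ne, n_inh_recorded=rec_ni)

    ce = np.concatenate(counts_e) if counts_e else np.zeros(0, dtype=np.int32)
    cinh = np.concatenate(counts_i) if counts_i else np.zeros(0, dtype=np.int32)
    wsteps = max(int(round(rate_window / dt)), 1)
    nwin = ce.size // wsteps
    if nwin > 0:
        re = ce[:nwin * wsteps].reshape(nwin, wsteps).sum(axis=1) / (rate_window * NE)
        ri = cinh[:nwin * wsteps].reshape(nwin, wsteps).sum(axis=1) / (rate_window * NI)
        rt = rate_window * (np.arange(nwin) + 1)
    else:
        re = ri = rt = np.zeros(0)
    rates = RateTrace(times=rt, exc=re, inh=ri, window=rate_window)

    return SimResult(raster=raster, rates=rates, weight_snapshots=snapshots,
                     final_weights=ee_w if plastic_on else None,
                     r_bar=rbar.copy() if plastic_on else None,
                     duration=sim_duration if stopped_at is None else stopped_at,
                     dt=dt, seed=seed,
                     aborted_at=stopped_at if aborted else None,
                     final_state={"V": V, "theta": theta, "g_ampa": g_a,
                                  "g_nmda": g_n, "g_gaba": g_g})


def population_rate(raster: SpikeRaster, window: float,
                    population: str = "exc") -> Tuple[np.ndarray, np.ndarray]:
    """Windowed population rate: spike count per window divided by
    ``window * population size``.  Returns ``(window right edges, rates)``."""
    if window <= 0:
        raise ConfigurationError("window must be positive")
    times, _, size = raster.select(population)
    if size == 0:
        raise ConfigurationError(f"no recorded neurons in population {population!r}")
    n_win = max(int(np.ceil(raster.duration / window - 1e-12)), 1)
    edges = window * np.arange(n_win + 1)
    counts, _ = np.histogram(times, bins=edges)
    return edges[1:], counts / (window * size)


@dataclass
class ISIStatistics:
    rates: np.ndarray      # per recorded neuron (Hz), silent neurons -> 0
    cv: np.ndarray         # per neuron with >= min_spikes spikes
    isis: np.ndarray       # pooled inter-spike intervals (s)
    all_silent: bool


def isi_statistics(raster: SpikeRaster, population: str = "exc",
                   min_spikes: int = 3) -> ISIStatistics:
    """Per-neuron firing rates, coefficients of variation of the
    inter-spike intervals (neurons with fewer than ``min_spikes`` spikes
    are excluded from the CV), and the pooled ISI sample."""
    times, ids, size = raster.select(population)
    if size == 0:
        raise ConfigurationError("empty population")
    if times.size == 0:
        warnings.warn("all-silent raster: empty ISI statistics", RuntimeWarning)
        return ISIStatistics(np.zeros(size), np.empty(0), np.empty(0), True)
    base = 0 if population != "inh" else raster.n_exc_total
    local = ids - base
    order = np.lexsort((times, local))
    t_sorted = times[order]
    id_sorted = local[order]
    same = id_sorted[1:] == id_sorted[:-1]
    d = np.diff(t_sorted)
    isis = d[same]
    counts = np.bincount(id_sorted, minlength=size)
    rates = counts / raster.duration
    cvs = []
    boundaries = np.flatnonzero(~same) + 1 if same.size else np.empty(0, int)
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [id_sorted.size]])
    for a, b in zip(starts, stops):
        if b - a >= min_spikes:
            seg = np.diff(t_sorted[a:b])
            m = seg.mean()
            if m > 0:
                cvs.append(seg.std() / m)
    return ISIStatistics(rates=rates, cv=np.asarray(cvs), isis=isis,
                         all_silent=False)


def detect_instability(trace_times: np.ndarray, rates: np.ndarray,
                       lower_bound: float = 0.1, upper_bound: float = 30.0,
                       quiet_window: float = 10.0,
                       tau_bar: Optional[float] = None) -> LifetimeResult:
    """Classify a rate trace: ``runaway`` once the rate exceeds
    ``upper_bound``, ``silent`` once it stays below ``lower_bound`` for
    ``quiet_window``, otherwise ``stable`` with lifetime equal to the trace
    duration."""
    if not (0 < lower_bound < upper_bound):
        raise ConfigurationError("need 0 < lower_bound < upper_bound")
    trace_times = np.asarray(trace_times, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if trace_times.size == 0:
        return LifetimeResult(lifetime=0.0, outcome="stable", tau_bar=tau_bar)
    window = trace_times[1] - trace_times[0] if trace_times.size > 1 else trace_times[0]
    run_idx = np.flatnonzero(rates > upper_bound)
    t_run = trace_times[run_idx[0]] if run_idx.size else np.inf
    k = max(int(round(quiet_window / window)), 1)
    below = rates < lower_bound
    t_sil = np.inf
    if below.size >= k:
        run = np.convolve(below.astype(int), np.ones(k, dtype=int), mode="valid")
        idx = np.flatnonzero(run == k)
        if idx.size:
            first = idx[0]
            t_sil = trace_times[first - 1] if first > 0 else 0.0
    if t_run <= t_sil and np.isfinite(t_run):
        return LifetimeResult(lifetime=float(t_run), outcome="runaway", tau_bar=tau_bar)
    if np.isfinite(t_sil):
        return LifetimeResult(lifetime=float(t_sil), outcome="silent", tau_bar=tau_bar)
    return LifetimeResult(lifetime=float(trace_times[-1]), outcome="stable",
                          tau_bar=tau_bar)


def epsp_probe(neuron_params: NeuronParams = NeuronParams(),
               weight: float = 0.16, duration: float = 0.5, dt: float = 1e-4,
               spike_time: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Voltage deflection ``V(t) - E_rest`` of a single neuron at rest
    receiving one presynaptic spike through a synapse of the given weight.

    Uses the same update order and forward-Euler scheme as the network
    kernel.  Returns ``(times, deflection)``."""
    p = neuron_params
    n = int(round(duration / dt))
    s0 = int(round(spike_time / dt))
    V = p.E_rest
    ga = gn = 0.0
    out = np.empty(n)
    ts = dt * (np.arange(n) + 1)
    for s in range(n):
        gn += dt / p.tau_nmda * (ga - gn)
        ga *= 1.0 - dt / p.tau_ampa
        ge = p.alpha_nmda * ga + (1.0 - p.alpha_nmda) * gn
        V += dt / p.tau_mem_exc * ((p.E_rest - V) + ge * (p.E_exc_rev - V))
        out[s] = V - p.E_rest
        if s == s0:
            ga += weight
    return ts, out
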