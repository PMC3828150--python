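"""Compiled inner loop of the spiking-network simulator.

One synchronous forward-Euler step (0.1 ms default) consists of
(1) decay of conductances, thresholds and plasticity traces,
(2) voltage integration, (3) threshold test and reset, and
(4) propagation of this step's spikes into target conductances, which
therefore become effective on the next step.  Membrane and threshold
equations use plain forward Euler; the linear trace equations use the exact
per-step decay factor so that the in-kernel plasticity matches the
event-driven engine to machine precision on identical spike trains.

Triplet plasticity on the recurrent excitatory (EE) block is applied in two
passes per step: first every weight update is computed from the trace
values *before* this step's increments (use-then-increment, with the slow
postsynaptic trace evaluated just before the current spike), then the
spiking neurons' own traces and rate estimates are incremented.

External drive is the superposition of ``n_ext`` independent Poisson
sources: per step a Poisson-distributed number of source events is drawn
and assigned to uniformly random sources.
"""
import numpy as np
from numba import njit

__all__ = ["run_chunk"]


@njit(cache=True)
def run_chunk(n_steps, dt, seed,
              NE, NI,
              # forward-Euler / decay constants
              f_ampa, f_gaba, dt_over_tau_nmda, f_theta,
              theta_rest, dtheta, dt_over_tm_e, dt_over_tm_i,
              E_rest, E_exc, E_inh, alpha,
              # state (length NE+NI, excitatory first)
              V, theta, g_a, g_n, g_g,
              # connectivity, CSR by presynaptic neuron (targets are
              # population-local indices)
              ee_ptr, ee_idx, ee_w,
              ei_ptr, ei_idx, ei_w,
              ie_ptr, ie_idx, ie_w,
              ii_ptr, ii_idx, ii_w,
              # external Poisson sources -> excitatory targets
              n_ext, ext_lam, ext_ptr, ext_idx, ext_w,
              # plasticity (EE block); CSC view maps into ee_w
              plastic_on, update_weights, metaplastic,
              ee_cptr, ee_cpre, ee_cmap,
              zp, zm, zs, rbar,
              f_zp, f_zm, f_zs, f_rbar,
              eta_w0_A3, eta_w0_A2ref, inv_kappa, beta, inv_tau_bar,
              w_min, w_max,
              # recording
              ecount, icount,
              rec_n_e, rec_n_i, rec_t, rec_id, rec_state, t0,
              spike_buf, abort_above, abort_window,
              sched_steps, sched_src, sched_state):
    np.random.seed(seed)
    N = NE + NI
    rec_pos = rec_state[0]
    rec_cap = rec_t.shape[0]
    rec_state[2] = -1
    roll_sum = 0
    for s in range(n_steps):
        # (1) decay
        for i in range(N):
            g_n[i] += dt_over_tau_nmda * (g_a[i] - g_n[i])
            g_a[i] *= f_ampa
            g_g[i] *= f_gaba
            theta[i] += f_theta * (theta_rest - theta[i])
        if plastic_on:
            for i in range(NE):
                zp[i] *= f_zp
                zm[i] *= f_zm
                zs[i] *= f_zs
                rbar[i] *= f_rbar
        # (2) integrate voltages; clamp to the reversal potentials (the
        # admissible range for nonnegative conductances), which also bounds
        # the forward-Euler overshoot at extreme conductances
        for i in range(NE):
            ge = alpha * g_a[i] + (1.0 - alpha) * g_n[i]
            v = V[i] + dt_over_tm_e * ((E_rest - V[i]) + ge * (E_exc - V[i])
                                       + g_g[i] * (E_inh - V[i]))
            if v < E_inh:
                v = E_inh
            elif v > E_exc:
                v = E_exc
            V[i] = v
        for i in range(NE, N):
            ge = alpha * g_a[i] + (1.0 - alpha) * g_n[i]
            v = V[i] + dt_over_tm_i * ((E_rest - V[i]) + ge * (E_exc - V[i])
                                       + g_g[i] * (E_inh - V[i]))
            if v < E_inh:
                v = E_inh
            elif v > E_exc:
                v = E_exc
            V[i] = v
        # (3) threshold test and reset
        nsp = 0
        ne_sp = 0
        for i in range(N):
            if V[i] >= theta[i]:
                spike_buf[nsp] = i
                nsp += 1
                if i < NE:
                    ne_sp += 1
                V[i] = E_rest
                theta[i] += dtheta
        ecount[s] = ne_sp
        icount[s] = nsp - ne_sp
        if abort_above > 0:
            # sustained-rate runaway check on a sliding window (a single
            # synchronous volley does not trip it)
            roll_sum += ne_sp
            if s >= abort_window:
                roll_sum -= ecount[s - abort_window]
            if roll_sum > abort_above:
                rec_state[0] = rec_pos
                rec_state[2] = s
                return
        # recording (subset raster)
        if rec_n_e > 0 or rec_n_i > 0:
            t = t0 + (s + 1) * dt
            for b in range(nsp):
                j = spike_buf[b]
                if (j < rec_n_e) or (j >= NE and j - NE < rec_n_i):
                    if rec_pos < rec_cap:
                        rec_t[rec_pos] = t
                        rec_id[rec_pos] = j
                        rec_pos += 1
                    else:
                        rec_state[1] += 1  # dropped
        # (3b) plasticity: weight updates then trace increments
        if plastic_on:
            if update_weights:
                for b in range(nsp):
                    j = spike_buf[b]
                    if j >= NE:
                        continue
                    zsj = zs[j]
                    # post role: potentiate incoming EE synapses
                    for q in range(ee_cptr[j], ee_cptr[j + 1]):
                        m = ee_cmap[q]
                        w = ee_w[m] + eta_w0_A3 * zp[ee_cpre[q]] * zsj
                        if w > w_max:
                            w = w_max
                        elif w < w_min:
                            w = w_min
                        ee_w[m] = w
                    # pre role: depress outgoing EE synapses
                    for q in range(ee_ptr[j], ee_ptr[j + 1]):
                        post = ee_idx[q]
                        if metaplastic:
                            a2 = eta_w0_A2ref * (rbar[post] * inv_kappa) ** beta
                        else:
                            a2 = eta_w0_A2ref
                        w = ee_w[q] - a2 * zm[post]
                        if w > w_max:
                            w = w_max
                        elif w < w_min:
                            w = w_min
                        ee_w[q] = w
            for b in range(nsp):
                j = spike_buf[b]
                if j < NE:
                    zp[j] += 1.0
                    zm[j] += 1.0
                    zs[j] += 1.0
                    rbar[j] += inv_tau_bar
        # (4) propagate spikes (effective next step)
        for b in range(nsp):
            j = spike_buf[b]
            if j < NE:
                for q in range(ee_ptr[j], ee_ptr[j + 1]):
                    g_a[ee_idx[q]] += ee_w[q]
                for q in range(ei_ptr[j], ei_ptr[j + 1]):
                    g_a[NE + ei_idx[q]] += ei_w[q]
            else:
                jj = j - NE
                for q in range(ie_ptr[jj], ie_ptr[jj + 1]):
                    g_g[ie_idx[q]] += ie_w[q]
                for q in range(ii_ptr[jj], ii_ptr[jj + 1]):
                    g_g[NE + ii_idx[q]] += ii_w[q]
        # external drive: Poisson sources, or a prescribed spike schedule
        # (ext_lam < 0) used for deterministic tests
        if ext_lam > 0.0:
            k = np.random.poisson(ext_lam)
            for _ in range(k):
                src = np.random.randint(0, n_ext)
                for q in range(ext_ptr[src], ext_ptr[src + 1]):
                    g_a[ext_idx[q]] += ext_w[q]
        elif ext_lam < 0.0:
            ptr = sched_state[0]
            while ptr < sched_steps.shape[0] and sched_steps[ptr] == s:
                src = sched_src[ptr]
                for q in range(ext_ptr[src], ext_ptr[src + 1]):
                    g_a[ext_idx[q]] += ext_w[q]
                ptr += 1
            sched_state[0] = ptr
    rec_state[0] = rec_pos
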