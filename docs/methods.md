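# Methods

`homeoplast` studies a single question: how fast must the homeostatic rate
detector of a plastic cortical network be for the asynchronous low-rate
background state to survive ongoing Hebbian learning?  It answers it twice —
by direct simulation of a conductance-based balanced spiking network with
triplet STDP, and by linear stability analysis of a two-dimensional
mean-field reduction — and provides the calibration machinery to compare the
two quantitatively.

## Network model

Leaky integrate-and-fire neurons with conductance-based synapses and a
relative refractory mechanism.  The membrane obeys

    tau_m dV/dt = (E_rest - V) + g_exc (E_exc - V) + g_gaba (E_inh - V),

with conductances in units of the leak conductance, `tau_m` = 20 ms
(excitatory) / 10 ms (inhibitory), `E_rest` = -70 mV, `E_exc` = 0 mV,
`E_inh` = -80 mV.  A spike fires when V crosses a dynamic threshold that
rests at -50 mV, jumps by 100 mV at each spike and relaxes back with a 5 ms
time constant; V resets to `E_rest`.  Excitatory synapses mix a fast AMPA
conductance (5 ms decay; presynaptic spikes add the synaptic weight) and a
slow NMDA component obtained by low-pass filtering the AMPA conductance
(100 ms) — the NMDA voltage dependence is omitted — combined as
`g_exc = 0.5 g_ampa + 0.5 g_nmda`.  Inhibition is a single GABA conductance
(10 ms).

The reference network has 20 000 excitatory and 5 000 inhibitory neurons,
every ordered pair connected independently with probability 5 % (no
self-connections), plus 2 500 external Poisson sources at 2 Hz projecting
to the excitatory population at 5 %.  Each excitatory neuron therefore
receives on average 1000 recurrent excitatory, 250 inhibitory and 125
external synapses — about 91 % of its input is recurrent.  Excitatory
weights are `w_EE = w_EI = w_ext = 0.16`; the single inhibitory strength
`w_IE = w_II = 0.98` was tuned once so that the static network settles into
the asynchronous irregular state at a mean excitatory rate of ~3 Hz (CV of
the inter-spike intervals ~0.95), which is the construction criterion of
the reference network; it is frozen thereafter.

### Integration and numerical choices

Forward Euler at `dt` = 0.1 ms.  Within a step: (1) decay conductances,
thresholds and plasticity traces; (2) integrate voltages; (3) threshold
test and reset; (4) propagate this step's spikes (they become effective on
the next step).  There are no axonal delays.  Two deliberate numerical
choices:

* **Voltage clamping.**  Voltages are clamped to `[E_inh, E_exc]` after
  each Euler step.  This is the admissible range for nonnegative
  conductances; without the clamp, forward Euler becomes oscillatory-
  unstable once `dt * g / tau_m > 2` (reachable during runaway episodes)
  and locks the network into an artificial saturated firing state.
* **Initial state.**  By default runs start at the balanced operating
  point: conductances at their mean-field values for the target rates
  (3 Hz excitatory, 6 Hz inhibitory by default) and voltages uniform
  between rest and threshold.  Starting from rest instead, the silent
  network ignites through a strongly synchronized population volley
  (external drive reaches only the excitatory population, so inhibition is
  recruited too late) and does not reach the asynchronous state.  `init="rest"`
  remains available for single-neuron and protocol work.
* **Trace decay.**  The linear plasticity-trace equations are advanced with
  the exact per-step factor `exp(-dt/tau)` rather than the Euler factor, so
  the in-kernel rule agrees with the event-driven engine to machine
  precision on identical spike trains.

External Poisson input is drawn per step as a Poisson-distributed number of
source events assigned to uniformly random sources — exactly equivalent to
independent Poisson processes per source.  A deterministic spike schedule
can be injected instead (used by the convergence and equivalence tests).
Runs are bit-reproducible from the master seed, which spawns independent
substreams for connectivity, initial conditions and the per-chunk kernel
RNG.

### Down-scaled presets

Full-scale 24 h runs are out of reach on a desk machine.
`scaled_network(factor)`
divides all populations by `factor` and multiplies the connection
probabilities by the same factor, preserving every mean in-degree and hence
the mean conductances.  Shared-input correlations grow with the factor and
the measured background rate drifts down mildly (about 2.9 Hz at factor 2,
2.5 Hz at factor 5, 2.2 Hz at factor 10, versus 3.1 Hz at full scale); the
CV of the ISI stays near 0.93.  Experiments additionally inflate the
relative learning rate `eta`, which shortens every plasticity timescale
(and `tau_crit`) proportionally; the homeostatic time constants of the
decay and scaling variants are shortened by the same factor to keep the
competition between processes unchanged.  Experiment metadata records both.

## Plasticity

Minimal all-to-all triplet STDP (visual-cortex parameter set): every pre
spike depresses the synapse by `A2_minus * z_minus(post)`; every post spike
potentiates it by `A3_plus * z_plus(pre) * z_slow(post)`, with the slow
postsynaptic trace read *just before* its own increment (use-then-
increment).  Trace time constants: `tau_plus` = 16.8 ms, `tau_minus` =
33.7 ms, `tau_y` = 114 ms; `A3_plus` = 6.5e-3; pair LTP and triplet LTD are
absent in the minimal set.  Updates act additively, scaled by `eta * w0`,
clipped to `[0, 1]`; structurally absent synapses never appear.  `eta = 1`
is the value fitted to slice experiments; network experiments default to
`eta = 6.25`, which reaches in one simulated day the degree of convergence
`eta = 1` would reach in 6.25 days.

Every neuron estimates its own rate as the low-pass filtered spike train
(`r_bar`: decays with `tau_bar`, jumps by `1/tau_bar` per spike).  The rate
detector starts at the target rate `kappa` in network simulations to avoid
a spurious LTD-free transient, and warmup runs (plasticity traces evolving,
weights frozen) let it settle further.

Homeostasis comes in three variants:

* **Metaplastic LTD** — the depression amplitude slides with the estimate,
  `A2_minus(r_bar) = A2_minus_ref (r_bar/kappa)^beta`, with
  `A2_minus_ref = A3_plus tau_plus tau_y kappa / tau_minus` fixed by the
  requirement that LTP and LTD cancel on average for uncorrelated Poisson
  firing at `kappa`.  The expected drift for Poisson pre/post rates (x, y)
  is `eta w0 A3+ tau+ tau_y x y (y - gamma(r_bar))` with the BCM sliding
  threshold `gamma(r_bar) = kappa (r_bar/kappa)^beta`.  `beta` defaults to
  2 (the choice that makes the priming-frequency dependence quadratic);
  the stability theory is independent of it.
* **Weight decay** — the metaplastic rule plus multiplicative decay
  `exp(-elapsed/tau_decay)`, applied in periodic batches (1 s default),
  which composes exactly to the continuous solution.  Default
  `tau_decay` = 10 h: at the network learning rate a 1 h decay is already
  strong enough to erase the background fixed point of the mean-field flow
  entirely, while at 10 h the fixed point survives at 2.95 Hz and the
  critical timescale shifts up by ~3 % (the "small positive shift" regime).
* **Synaptic scaling** — LTD amplitude fixed at its reference value, and
  each neuron's afferent weights multiplied periodically by
  `exp(elapsed/tau_scaling * (1 - (r_bar/kappa)^n))`.  The exponent
  defaults to `n = 4`: with a linear term an additional unstable fixed
  point of the mean-field flow sits just above the background rate, and
  `n = 2` still leaves one below the response pole, whereas `n = 4`
  removes the extra high-rate fixed point.  The linearization at the fixed
  point — and therefore every stability statement — does not depend on `n`.

## Mean-field model and stability

The static network response is linearised as `r = F0 / (1 - F1 w)` (offset
`F0` in Hz, dimensionless gain `F1 w`, pole treated as a hard domain
boundary).  Averaging the triplet rule over Poisson statistics turns it
into the rate rule `dw/dt = eta w0/(tau_w kappa^3) r^2 (r - gamma(r_bar))`
with the effective plasticity timescale
`tau_w = 1/(A3+ tau+ tau_y kappa^3)` (~2975 s at 3 Hz).  Chaining through
`dr/dw` closes the system in `(r, r_bar)`:

    dr/dt     = C r^4 (r - gamma(r_bar)) + variant terms,
    dr_bar/dt = (r - r_bar) / tau_bar,      C = eta w0 F1 / (F0 tau_w kappa^3).

Fixed points: the quiescent state at the origin and the background state at
`(kappa, kappa)` (pulled slightly below `kappa` by a weight decay; located
by root finding on the diagonal, taking the root nearest `kappa`).  The
Jacobian at the background fixed point is, for the metaplastic rule,
`[[a, -beta a], [1/tau_bar, -1/tau_bar]]` with
`a = eta w0 F1 kappa / (F0 tau_w)`; its trace changes sign at

    tau_crit = 1/a = F0 tau_w / (eta w0 F1 kappa),

and the determinant `(beta - 1) a / tau_bar` is positive for `beta > 1`, so
the crossing is oscillatory (nonvanishing imaginary parts) and the
background state is stable exactly for `tau_bar < tau_crit` — independent
of `beta`.  Because `tau_w` scales as `kappa^-3`, `tau_crit` falls off with
the fourth power of the background rate.  With weight decay the same trace
condition is evaluated at the shifted fixed point (exact, matching the
eigenvalue bisection to better than 1e-6, and slightly above the decay-free
value).  With synaptic scaling the condition `tau_bar < tau_crit` is
necessary but not sufficient: the determinant also demands
`tau_scaling < n (kappa - F0) tau_crit / F0`, beyond which a saddle
destabilises the state regardless of the detector; very small
`tau_scaling` instead makes the eigenvalues complex (oscillations) without
losing stability.

All closed forms are validated in the test suite against centered-
difference Jacobians (1e-8), a generic eigensolver (1e-10) and bisection on
the maximal real eigenvalue part (1e-6 relative), since none of them is
trusted as a transcription.  Phase-plane work (trajectories at relative
tolerance 1e-8, nullclines as solved zero-level sets, separatrix by ray
bisection from the fixed point with a divergence radius of `100 kappa`) is
plumbing around these flows; the separatrix algorithm is the package's own
choice, as is the criticality tolerance `|max Re lambda| < 1e-10 s^-1`.

## Calibration and the stability transition

`calibrate_network` measures the static rate response by uniformly
rescaling the EE weights with plasticity disabled (each point: settle, then
measure; runaway points flagged, not fatal) and fits `F0/(1 - F1 w)` by
nonlinear least squares on a narrow, asymmetric interval around the
operating weight (default 0.88–1.06 of `w_EE`): the response pole sits only
a few percent above the operating point and the linearised model breaks
down at higher rates where refractoriness saturates the response.  On the
factor-5 network this yields `F0 ~ 0.2 Hz`, `F1 w_EE ~ 0.93` and a
calibrated `tau_crit` of ~38 s at `eta = 6.25` — seconds to minutes.

`sweep_tau_critical` then runs the plastic network across a `tau_bar` grid
and classifies each run (runaway once the 1 s population rate exceeds
10 kappa = 30 Hz; silent when it stays below 0.1 Hz for 10 s — the
operationalisation of "drops to zero", since no numeric threshold is
recoverable; stable otherwise).  Desk-scale sweeps (factor-5 network,
`eta` = 20–50, 60–150 s of biological time per point) show a sharp step in
lifetimes: runs below the transition survive the full duration, runs above
it run away within seconds to tens of seconds, and the transition bracket
contains, or sits just below, the calibrated mean-field `tau_crit`.  At
full scale the mean-field value is expected to consistently *over*-estimate
the simulated transition (the theory ignores fluctuations and the shrinking
basin of attraction near criticality, both of which push the spiking
network over the edge earlier); that strict ordering is consistent with
the desk-scale brackets but not resolvable on a factor-2 grid, so the tests
assert the step shape, that the guaranteed-stable regime lies below the
theoretical value, and order-of-magnitude agreement.

## Weight distributions

Under the purely additive metaplastic rule, ongoing background plasticity
drives individual weights diffusively to the bounds: the steady-state
distribution is bimodal with mass at both limits.  A slow weight decay or
synaptic scaling re-centres the distribution into a unimodal shape.  The
tests reproduce this at desk scale with the factor-10 network, `eta = 50`
and `w_max = 0.4` (reducing the upper bound — one of the exposed
robustness knobs — shortens the time for weights to reach it roughly by
the square of the distance): after 10 minutes of biological time the
metaplastic run holds >5 % of synapses at the lower and >1.5 % at the
upper bound, while the decay (`tau_decay` = 900 s at this `eta`) and
scaling (`tau_bar` = 1 s, `tau_scaling` = 150 s) runs keep the upper bound
essentially empty.  The bimodality statistic is the smaller of the two
boundary-bin masses divided by the deepest interior-valley bin (floored at
`1/(10 bins)`); it is a frozen, documented choice of summary, not a claim
of optimality.  The scaling variant is noticeably more fragile at desk
scale: too-fast scaling overshoots into runaway or silence, matching the
narrow stable window the theory predicts for it.

## Priming protocol

Because the metaplastic rule changes its LTD amplitude on the detector
timescale, plasticity protocols depend on the cell's recent activity.  The
protocol driver reproduces this: 75 post–pre pairs at 5 Hz with a -10 ms
offset (LTD direction) on an isolated synapse, either from quiescence
(`r_bar` starts at 0 — the documented convention for the protocol's
baseline) or after priming (regular postsynaptic firing at a given
frequency and duration, terminated by 1 s of silence so the fast triplet
traces decay).  With `tau_bar` = 60 s, priming at 3 Hz for 100 s changes
the depression ~16-fold while the reversed (+10 ms, LTP) protocol changes
by <1 %.  The dependence on priming frequency is quadratic (`beta` = 2)
and on priming duration a saturating (squared) exponential with the
detector's time constant — the package's desk-scale rendering of the
priming predictions.

## Synthetic data and oracles

All inputs are generated: homogeneous Poisson trains (deterministic per
seed and index), regular trains, pairing protocols, and seeded random
networks.  Two independent oracles back the plasticity engines: a
dense-grid integrator (spikes binned to a 1 µs grid, traces advanced with
exact per-step exponential factors via `scipy.signal.lfilter` — an
exponential integrator, chosen because plain Euler at 1 µs cannot reach
the 1e-9 cross-implementation tolerance the comparisons demand) and a
Monte-Carlo drift estimator that walks merged Poisson event sequences with
the rate estimate clamped (isolating the STDP kernel under the
stationarity assumption).  Neither shares code with the production
engines.

## What the tests do and do not show

Passing tests demonstrate: the closed-form theory is internally correct
against generic numerics; the spiking implementation matches its
event-driven reference to machine precision and converges in `dt`; the
full-scale static network reproduces the balanced 3 Hz asynchronous
irregular state; and the desk-scale plastic network reproduces the
qualitative and order-of-magnitude quantitative structure of the full
study (sharp stability transition near the calibrated prediction,
bimodal/unimodal weight distributions, priming phenomenology).  They do
not certify 24 h full-scale behaviour (in particular the slow "late"
instability of long runs is out of scope), nor behaviour under correlated
external input, which the mean-field reduction explicitly ignores.

## Known limitations

* The mean-field reduction ignores noise, correlations and finite-size
  fluctuations; its predictions are upper-bound-flavoured near criticality
  where the basin of attraction shrinks.
* Down-scaled networks have larger shared-input correlations and slightly
  lower background rates; quantitative constants (e.g. fitted `F0`, `F1`)
  are preset-specific and should be re-calibrated per configuration.
* Inhibitory weights are a tuned quantity (the construction criterion is
  the 3 Hz balanced state), not an independently measured one.
* No inhibitory plasticity, short-term plasticity, adaptation beyond the
  relative refractory threshold, transmission delays, or NMDA voltage
  dependence.
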