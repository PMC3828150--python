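# homeoplast

Hebbian plasticity is a positive feedback loop: strengthening excitatory
synapses raises firing rates, which strengthens the synapses further.  In
recurrent network models this destabilises the low-rate asynchronous
background state unless a homeostatic mechanism counteracts it — and every
homeostatic mechanism relies on a *rate detector*, a low-pass filter with
time constant τ̄ by which a neuron estimates its own activity.
`homeoplast` is a toolkit for asking how fast that detector must be.  It is
aimed at computational neuroscientists who want a tested, reusable version
of this analysis: a balanced-network spiking simulator with homeostatic
triplet STDP, the matching two-dimensional mean-field theory with
closed-form stability results, and the calibration machinery to compare the
two.

## The model in brief

* **Network**: 20 000 excitatory + 5 000 inhibitory conductance-based LIF
  neurons (AMPA/NMDA + GABA, adaptive thresholds), 5 % random connectivity,
  2 500 external Poisson sources at 2 Hz; tuned to the asynchronous
  irregular balanced state at ≈3 Hz.
* **Plasticity**: minimal all-to-all triplet STDP on recurrent excitatory
  synapses (τ₊ = 16.8 ms, τ₋ = 33.7 ms, τ_y = 114 ms, A₃⁺ = 6.5·10⁻³), with
  homeostasis as (i) a metaplastic LTD amplitude
  A₂⁻(r̄) = A₂⁻ᵣₑf (r̄/κ)^β sliding with the rate estimate r̄ (a BCM rule
  with target rate κ = 3 Hz), (ii) the same rule plus slow weight decay, or
  (iii) triplet STDP with multiplicative synaptic scaling.
* **Mean field**: the network response linearises as r = F₀/(1 − F₁w);
  averaging the triplet rule over Poisson statistics gives an effective
  plasticity timescale τ_w = 1/(A₃⁺τ₊τ_y κ³) ≈ 3000 s, and the coupled
  (r, r̄) system is linearly stable iff the rate detector is fast enough:

      τ̄ < τ_crit = F₀ τ_w / (η w₀ F₁ κ)  ∝  κ⁻⁴.

  For realistic parameters τ_crit is seconds to minutes — far faster than
  classically reported homeostatic mechanisms.

See `docs/methods.md` for the full model description, parameter tables,
numerical choices and limitations.

## Worked example

```python
from homeoplast import (MFParams, TripletParams, NetworkConfig,
                        build_network, simulate, isi_statistics)
from homeoplast import meanfield as mf

# closed-form stability of the background state (metaplastic rule)
p = MFParams()            # F0=0.3 Hz, F1=5, eta=6.25, kappa=3 Hz
tp = TripletParams()
print(f"tau_w     = {mf.effective_tau_w(tp):8.1f} s")
print(f"tau_crit  = {mf.critical_tau(p, 'metaplastic_ltd'):8.2f} s")
rep = mf.stability_report(p.replace(tau_bar=30.0), 'metaplastic_ltd')
print(f"tau_bar=30 s stable: {rep.stable}")

# the spiking network in its balanced background state (static weights)
net = build_network(NetworkConfig(seed=1))
res = simulate(net, duration=14.0, warmup=6.0, seed=101,
               record_raster=(2000, 0))
st = isi_statistics(res.raster)
print(f"mean excitatory rate = {res.rates.exc.mean():.2f} Hz, "
      f"CV ISI = {st.cv.mean():.2f}")
```

prints

```
tau_w     =   2975.1 s
tau_crit  =    59.50 s
tau_bar=30 s stable: True
mean excitatory rate = 3.24 Hz, CV ISI = 0.96
```

i.e. with these constants the rate detector must act within about a minute
(`tau_crit` ≈ 59.5 s; a 30 s detector is safe), and the full 25 000-neuron
network indeed sits at ≈3 Hz with Poisson-like irregular firing.  The same
workflow scales down: `scaled_network(5)` gives a 5 000-neuron preset with
identical in-degrees for desk-scale plasticity experiments, and
`calibration.calibrate_network` extracts (F₀, F₁) from a rate scan so the
mean-field prediction can be compared against `calibration.sweep_tau_critical`,
the spiking stability sweep.

A thin CLI wraps the same functions:

```
homeoplast meanfield --variant metaplastic --tau-bar-sweep 1:200:50 --out sweep.tsv
homeoplast calibrate --scale 5 --seed 1 --out calib/
homeoplast experiment --preset priming --seed 1 --out priming/
```

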