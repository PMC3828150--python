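"""Parameter containers for the network, plasticity and mean-field models.

All quantities are in SI units internally (seconds, volts, Hz); synaptic
weights and conductances are dimensionless (in units of the leak
conductance).  Defaults reproduce the reference configuration of the study:
a 25 000-neuron conductance-based balanced network with triplet STDP on the
recurrent excitatory synapses and a homeostatic rate detector with time
constant ``tau_bar``.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "NeuronParams",
    "NetworkConfig",
    "TripletParams",
    "HomeostasisConfig",
    "MFParams",
    "VARIANTS",
    "full_scale_network",
    "scaled_network",
]

VARIANTS = ("metaplastic_ltd", "weight_decay", "synaptic_scaling")


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire neuron with conductance synapses and a
    relative refractory (adaptive threshold) mechanism.

    The excitatory conductance is a weighted mixture of a fast AMPA
    component and a slow NMDA component obtained by low-pass filtering the
    AMPA conductance; the NMDA voltage dependence is omitted.
    """

    tau_mem_exc: float = 20e-3
    tau_mem_inh: float = 10e-3
    E_rest: float = -70e-3
    E_exc_rev: float = 0.0
    E_inh_rev: float = -80e-3
    theta_rest: float = -50e-3
    delta_theta: float = 100e-3
    tau_theta: float = 5e-3
    tau_ampa: float = 5e-3
    tau_gaba: float = 10e-3
    tau_nmda: float = 100e-3
    alpha_nmda: float = 0.5

    def __post_init__(self):
        for name in ("tau_mem_exc", "tau_mem_inh", "tau_theta", "tau_ampa",
                     "tau_gaba", "tau_nmda"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (self.E_inh_rev < self.E_rest < self.theta_rest < self.E_exc_rev):
            raise ConfigurationError(
                "voltages must satisfy E_inh_rev < E_rest < theta_rest < E_exc_rev")
        if not 0.0 <= self.alpha_nmda <= 1.0:
            raise ConfigurationError("alpha_nmda must lie in [0, 1]")


@dataclass(frozen=True)
class NetworkConfig:
    """Population sizes, sparse random connectivity and static weights.

    ``w_ie``/``w_ii`` (the single inhibitory synaptic strength) were tuned
    once so that the static network settles into the asynchronous irregular
    balanced state at a mean excitatory rate of ~3 Hz, which is the
    criterion by which the reference network was constructed.
    """

    N_exc: int = 20000
    N_inh: int = 5000
    N_ext: int = 2500
    ext_rate: float = 2.0
    p_conn: float = 0.05
    p_ext: float = 0.05
    w_ee: float = 0.16
    w_ei: float = 0.16
    w_ie: float = 0.98
    w_ii: float = 0.98
    w_ext: float = 0.16
    seed: int = 1

    def __post_init__(self):
        if min(self.N_exc, self.N_inh, self.N_ext) <= 0:
            raise ConfigurationError("population sizes must be positive")
        for name in ("p_conn", "p_ext"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("w_ee", "w_ei", "w_ie", "w_ii", "w_ext"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.ext_rate < 0:
            raise ConfigurationError("ext_rate must be nonnegative")


def full_scale_network(**overrides) -> NetworkConfig:
    """The full reference network: 20 000 E / 5 000 I neurons, 5 %
    connectivity, 2 500 external Poisson sources at 2 Hz."""
    return NetworkConfig(**overrides)


def scaled_network(factor: int = 5, **overrides) -> NetworkConfig:
    """Down-scaled preset preserving every mean in-degree (and hence the
    mean synaptic conductance) by raising the connection probability by the
    same factor by which the populations shrink.

    ``factor=5`` gives 4 000 E / 1 000 I at 25 % connectivity; ``factor=10``
    gives 2 000 E / 500 I at 50 %.  Statistics of the balanced state carry
    over (shared-input correlations are somewhat larger).
    """
    base = NetworkConfig()
    if factor < 1 or base.N_exc % factor or base.N_inh % factor or base.N_ext % factor:
        raise ConfigurationError("factor must divide all population sizes")
    p = base.p_conn * factor
    if p > 1.0:
        raise ConfigurationError("factor too large: connectivity would exceed 1")
    cfg = dict(
        N_exc=base.N_exc // factor,
        N_inh=base.N_inh // factor,
        N_ext=base.N_ext // factor,
        p_conn=p,
        p_ext=base.p_ext * factor,
    )
    cfg.update(overrides)
    return NetworkConfig(**cfg)


@dataclass(frozen=True)
class TripletParams:
    """Minimal all-to-all triplet STDP rule (visual-cortex parameter set).

    Potentiation is a pure triplet effect (pre--post--post, amplitude
    ``A3_plus`` acting on the fast presynaptic trace ``z_plus`` and the slow
    postsynaptic trace ``z_slow``); depression is a pair effect (post--pre,
    amplitude ``A2_minus``) acting on the fast postsynaptic trace
    ``z_minus``.  The pair-LTP and triplet-LTD amplitudes of the general
    rule are zero in this minimal set.

    ``A2_minus_ref`` defaults to the value at which LTP and LTD cancel on
    average for uncorrelated Poisson firing at the target rate ``kappa``:
    ``A3_plus * tau_plus * tau_y * kappa / tau_minus``.

    ``eta`` converts the dimensionless rule to the weight scale of the
    network (weight updates are ``eta * w0 *`` rule); ``eta = 1``
    corresponds to the learning rate fitted to slice data, the network
    default of 6.25 trades biological realism for convergence within a day
    of biological time.
    """

    tau_plus: float = 16.8e-3
    tau_minus: float = 33.7e-3
    tau_y: float = 114e-3
    A3_plus: float = 6.5e-3
    A2_minus_ref: Optional[float] = None
    eta: float = 6.25
    w0: float = 0.16
    w_min: float = 0.0
    w_max: float = 1.0
    kappa: float = 3.0

    def __post_init__(self):
        for name in ("tau_plus", "tau_minus", "tau_y"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not self.w_min < self.w0 < self.w_max:
            raise ConfigurationError("must have w_min < w0 < w_max")
        if self.eta <= 0:
            raise ConfigurationError("eta must be positive")
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be positive")
        if self.A2_minus_ref is None:
            object.__setattr__(self, "A2_minus_ref", self.cancellation_ltd_amplitude())
        if self.A2_minus_ref < 0:
            raise ConfigurationError("A2_minus_ref must be nonnegative")

    def cancellation_ltd_amplitude(self) -> float:
        """LTD amplitude for which the expected Poisson drift vanishes at
        pre = post = rate-estimate = ``kappa``."""
        return self.A3_plus * self.tau_plus * self.tau_y * self.kappa / self.tau_minus

    def replace(self, **kw) -> "TripletParams":
        # A2_minus_ref tracks the cancellation condition unless pinned explicitly
        if "A2_minus_ref" not in kw and self.A2_minus_ref == self.cancellation_ltd_amplitude():
            kw.setdefault("A2_minus_ref", None)
        return replace(self, **kw)


@dataclass(frozen=True)
class HomeostasisConfig:
    """Selects the homeostatic mechanism and its timescales.

    ``tau_bar`` is the time constant of the rate detector (the exponential
    low-pass filter by which each neuron estimates its own firing rate); it
    is the bifurcation parameter of the study.

    variants
      ``metaplastic_ltd``   LTD amplitude slides with the rate estimate,
                            ``A2_minus(rbar) = A2_minus_ref (rbar/kappa)**beta``.
      ``weight_decay``      metaplastic rule plus a slow exponential weight
                            decay with time constant ``tau_decay``.
      ``synaptic_scaling``  LTD amplitude fixed at its reference value;
                            afferent weights of neuron *i* are multiplicatively
                            scaled at rate ``(1 - (rbar_i/kappa)**scaling_exponent)
                            / tau_scaling``.

    Decay and scaling are applied in periodic multiplicative batches every
    ``apply_period`` seconds, a faithful approximation of the continuous
    process as long as ``apply_period`` is much shorter than the decay and
    scaling time constants.
    """

    variant: str = "metaplastic_ltd"
    tau_bar: float = 10.0
    beta: float = 2.0
    tau_decay: float = 36000.0
    tau_scaling: float = 600.0
    scaling_exponent: float = 4.0
    apply_period: float = 1.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.tau_bar <= 0:
            raise ConfigurationError("tau_bar must be positive")
        if self.tau_decay <= 0 or self.tau_scaling <= 0:
            raise ConfigurationError("tau_decay and tau_scaling must be positive")
        if self.apply_period <= 0:
            raise ConfigurationError("apply_period must be positive")
        if self.apply_period > 0.1 * min(self.tau_decay, self.tau_scaling):
            raise ConfigurationError(
                "apply_period must be much shorter than tau_decay/tau_scaling")


@dataclass(frozen=True)
class MFParams:
    """Parameters of the two-dimensional mean-field system in the state
    (population rate r, rate estimate rbar).

    The static network response is ``r = F0 / (1 - F1 w)`` with offset
    ``F0`` (Hz) and dimensionless recurrent gain ``F1 w``; ``tau_w`` is the
    effective plasticity timescale obtained by averaging the triplet rule
    over Poisson statistics, ``1 / (A3_plus tau_plus tau_y kappa**3)``.
    ``decay_rate = 1/tau_decay`` (0 disables the decay term).
    """

    F0: float = 0.3
    F1: float = 5.0
    tau_w: float = 2975.0
    eta: float = 6.25
    kappa: float = 3.0
    tau_bar: float = 10.0
    beta: float = 2.0
    decay_rate: float = 0.0
    tau_scaling: float = 600.0
    scaling_exponent: float = 4.0
    w0: float = 0.16

    def __post_init__(self):
        if self.F0 <= 0:
            raise ConfigurationError("F0 must be positive")
        if self.tau_w <= 0 or self.tau_bar <= 0:
            raise ConfigurationError("tau_w and tau_bar must be positive")
        if self.eta <= 0 or self.kappa <= 0:
            raise ConfigurationError("eta and kappa must be positive")
        if self.decay_rate < 0:
            raise ConfigurationError("decay_rate must be nonnegative")
        if self.tau_scaling <= 0:
            raise ConfigurationError("tau_scaling must be positive")

    def replace(self, **kw) -> "MFParams":
        return replace(self, **kw)
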