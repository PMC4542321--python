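"""Parameter containers for the spiking-network simulation.

Unit system: mV, ms, nA, MOhm.  With currents in nA and the membrane
resistance in MOhm, ``R_m * I`` is in mV; synaptic couplings ``g`` carry
nA*ms so the ``exp(-t/tau_syn)/tau_syn`` kernel yields nA, and the layer-4
rate is converted from Hz to spikes/ms inside the drive formula.  This makes
the published default values usable verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "FeedforwardParams",
    "RecurrentParams",
    "STDPParams",
    "SimProtocol",
    "PlasticitySchedule",
    "DEFAULT_ANGLES_DEG",
]

# The nine-stimulus protocol: 0..160 deg in 20 deg steps.
DEFAULT_ANGLES_DEG = tuple(float(a) for a in range(0, 180, 20))


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire membrane parameters."""

    tau: float = 20.0  # membrane time constant, ms
    r_m: float = 38.3  # membrane resistance, MOhm
    v_t: float = 30.0  # spike threshold, mV
    v_reset: float = 0.0  # post-spike reset, mV

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.v_t <= self.v_reset:
            raise ValueError("threshold must exceed reset")


@dataclass(frozen=True)
class FeedforwardParams:
    """Layer-4 drive: a constant tuned current per Eq.-of-motion input.

    I_L4 = g_al * k_al * fr_l(1/ms) * (1 + 2 rho cos(2 (theta_stim - theta_i)))

    ``ff_ref_k``: if not None, the drive is additionally scaled by
    sqrt(K / ff_ref_k) so that sweeps of the recurrent in-degree K follow
    balanced scaling (all input components grow as sqrt(K)).  At the default
    K = ff_ref_k = 500 the factor is 1 and the published numbers apply
    verbatim.
    """

    g_al: float = 1.65  # feed-forward efficacy, nA*ms
    k_al: int = 250  # number of feed-forward synapses
    fr_l: float = 15.0  # mean layer-4 rate, Hz
    rho_e: float = 0.06  # input modulation, excitatory targets
    rho_i: float = 0.06  # input modulation, inhibitory targets
    ff_ref_k: float | None = 500.0

    def __post_init__(self):
        for name, rho in (("rho_e", self.rho_e), ("rho_i", self.rho_i)):
            if not 0.0 <= rho <= 0.5:
                raise ValueError(f"{name}={rho} outside [0, 0.5]; drive would go negative")

    def rho(self, pop: str) -> float:
        return self.rho_e if pop == "E" else self.rho_i


@dataclass(frozen=True)
class RecurrentParams:
    """Recurrent couplings (signed, G convention) and background drive.

    Couplings scale as g_AB = G_AB / sqrt(K); the background current is
    sqrt(K) * I_back_A, the net effect of K excitatory inputs each of
    strength ~1/sqrt(K).
    """

    g_ee: float = 32.0
    g_ei: float = -96.0
    g_ie: float = 96.0
    g_ii: float = -128.0
    tau_syn_e: float = 25.0  # ms; long to fold NMDA into AMPA
    tau_syn_i: float = 4.0  # ms
    k: float = 500.0  # mean recurrent in-degree
    i_back_e: float = 0.12  # nA (per sqrt(K))
    i_back_i: float = 0.12  # nA (per sqrt(K))

    def __post_init__(self):
        if self.tau_syn_e <= 0 or self.tau_syn_i <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.k < 0:
            raise ValueError("K must be nonnegative")

    def g_scaled(self, post: str, pre: str) -> float:
        """g_AB = G_AB / sqrt(K), signed."""
        g = {("E", "E"): self.g_ee, ("E", "I"): self.g_ei,
             ("I", "E"): self.g_ie, ("I", "I"): self.g_ii}[(post, pre)]
        return g / np.sqrt(self.k) if self.k > 0 else 0.0

    def magnitudes(self) -> dict[str, float]:
        return {
            "ee": abs(self.g_ee), "ei": abs(self.g_ei),
            "ie": abs(self.g_ie), "ii": abs(self.g_ii),
        }


@dataclass(frozen=True)
class STDPParams:
    """Multiplicative pair-based STDP with exponential windows.

    Pre-before-post potentiates by ``a_plus * exp(-dt/tau_plus) * (2 - w)``,
    post-before-pre depresses by ``a_minus * exp(-dt/tau_minus) * w``
    (``a_minus < 0``); the soft bounds keep ``w`` in ``[0, 2]``.  The window
    integral ``alpha = a_plus tau_plus + a_minus tau_minus`` controls the
    mean drift and is derived, never set.
    """

    a_plus: float = 0.0128
    a_minus: float = -0.0045
    tau_plus: float = 30.0  # ms
    tau_minus: float = 40.0  # ms
    w_max: float = 2.0

    def __post_init__(self):
        if self.a_plus < 0 or self.a_minus > 0:
            raise ValueError("expected a_plus >= 0 >= a_minus")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP window time constants must be positive")

    @property
    def alpha(self) -> float:
        """Window integral a+ tau+ + a- tau-, in ms."""
        return self.a_plus * self.tau_plus + self.a_minus * self.tau_minus


@dataclass(frozen=True)
class SimProtocol:
    """Integration step, run length, and the stimulus set."""

    dt: float = 0.05  # ms
    t_total: float = 20_000.0  # ms
    t_transient: float = 100.0  # ms, discarded from rate estimates
    angles_deg: tuple = DEFAULT_ANGLES_DEG
    seed: int = 0
    max_rate_hz: float = 250.0  # spike-buffer headroom per neuron

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.t_transient < self.t_total:
            raise ValueError("transient must be shorter than the run")


@dataclass(frozen=True)
class PlasticitySchedule:
    """Plastic phase at a single training orientation, then frozen weights.

    The published protocol trains for the first two thirds of a run and
    measures on the last third; here the measurement is the full multi-angle
    protocol run on the frozen graph so the selectivity index is well
    defined.
    """

    t_plastic: float = 13_333.0  # ms with plasticity on
    t_measure: float = 6_667.0  # ms per measurement angle, frozen weights
    theta_train_deg: float = 0.0

    def __post_init__(self):
        if self.t_plastic <= 0 or self.t_measure <= 0:
            raise ValueError("schedule durations must be positive")
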