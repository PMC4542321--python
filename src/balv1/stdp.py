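"""Multiplicative pair-based STDP on excitatory-presynaptic synapses.

Every pre/post spike pair contributes (all-to-all pairing): a post spike at
``t_post`` potentiates by ``a_plus exp(-(t_post-t_pre)/tau_plus) (2 - w)``
summed over all earlier pre spikes, and a pre spike depresses by
``a_minus exp(-(t_pre-t_post)/tau_minus) w`` summed over all earlier post
spikes (``a_minus < 0``).  Simultaneous (step-quantized) spikes contribute
nothing.  The multiplicative factors use the weight current at the
triggering spike, so the exponential-window pairing is implemented exactly
by two decaying traces; :func:`stdp_all_pairs` is the explicit double-loop
reference for that equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityGraph
from .geometry import OrientationLayout
from .params import (
    FeedforwardParams,
    NeuronParams,
    PlasticitySchedule,
    RecurrentParams,
    STDPParams,
)
from .simulate import _external_current, flatten_graph, run_single

__all__ = [
    "stdp_update",
    "stdp_all_pairs",
    "stdp_trace",
    "apply_plasticity",
    "PlasticityResult",
    "mean_field_dw",
]


def stdp_update(w, delta_t, p: STDPParams):
    """Single-pair weight change for ``delta_t = t_post - t_pre`` (ms).

    Vectorized over ``w`` and ``delta_t``; ``delta_t == 0`` gives 0.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > p.w_max):
        raise ValueError(f"efficacy outside [0, {p.w_max}]")
    delta_t = np.asarray(delta_t, dtype=float)
    pot = p.a_plus * np.exp(-delta_t / p.tau_plus) * (p.w_max - w)
    dep = p.a_minus * np.exp(delta_t / p.tau_minus) * w
    dw = np.where(delta_t > 0, pot, np.where(delta_t < 0, dep, 0.0))
    return dw if dw.ndim else float(dw)


def _merge_events(pre_times, post_times):
    """Chronological (time, is_post) event list.

    At tied times the post (potentiation) event is processed first, matching
    the simulation kernel; tied pairs never pair with each other.
    """
    t = np.concatenate([np.asarray(post_times, float), np.asarray(pre_times, float)])
    kind = np.concatenate(
        [np.ones(len(post_times), dtype=bool), np.zeros(len(pre_times), dtype=bool)]
    )
    order = np.argsort(t, kind="stable")
    return t[order], kind[order]


def stdp_all_pairs(pre_times, post_times, w0: float, p: STDPParams) -> float:
    """Explicit all-pairs reference: process spikes chronologically and, at
    each spike, loop over every earlier spike of the other train.

    Pairs at identical (quantized) times are skipped.  Weight clipped to
    [0, w_max] after each triggering spike.
    """
    t, is_post = _merge_events(pre_times, post_times)
    w = float(w0)
    for i in range(t.size):
        s = 0.0
        if is_post[i]:
            for j in range(t.size):
                if not is_post[j] and t[j] < t[i]:
                    s += np.exp(-(t[i] - t[j]) / p.tau_plus)
            w += p.a_plus * s * (p.w_max - w)
        else:
            for j in range(t.size):
                if is_post[j] and t[j] < t[i]:
                    s += np.exp(-(t[i] - t[j]) / p.tau_minus)
            w += p.a_minus * s * w
        w = min(max(w, 0.0), p.w_max)
    return w


def stdp_trace(pre_times, post_times, w0: float, p: STDPParams) -> float:
    """Trace-based online evaluation of the same rule on two spike trains.

    Mirrors the simulation kernel: one presynaptic and one postsynaptic
    exponential trace, updated after the pairings of each event time so that
    simultaneous spikes never see each other.
    """
    t, is_post = _merge_events(pre_times, post_times)
    w = float(w0)
    x_pre = 0.0  # sum of exp(-(t - t_pre)/tau_plus) over past pre spikes
    y_post = 0.0
    t_last = -np.inf
    i = 0
    while i < t.size:
        # advance traces to this event time
        if np.isfinite(t_last):
            dt = t[i] - t_last
            x_pre *= np.exp(-dt / p.tau_plus)
            y_post *= np.exp(-dt / p.tau_minus)
        t_last = t[i]
        j = i
        while j < t.size and t[j] == t[i]:
            j += 1
        for e in range(i, j):  # pairings against strictly earlier spikes
            if is_post[e]:
                w += p.a_plus * x_pre * (p.w_max - w)
            else:
                w += p.a_minus * y_post * w
            w = min(max(w, 0.0), p.w_max)
        for e in range(i, j):
            if is_post[e]:
                y_post += 1.0
            else:
                x_pre += 1.0
        i = j
    return w


@dataclass
class PlasticityResult:
    graph: ConnectivityGraph  # fresh graph carrying the final efficacies
    spike_idx: np.ndarray
    spike_t: np.ndarray
    theta_train_deg: float
    t_plastic: float


def apply_plasticity(
    graph: ConnectivityGraph,
    layout: OrientationLayout,
    neuron: NeuronParams,
    ff: FeedforwardParams,
    rec: RecurrentParams,
    stdp: STDPParams,
    schedule: PlasticitySchedule,
    seed,
    dt: float = 0.05,
    max_rate_hz: float = 250.0,
) -> PlasticityResult:
    """Run the plastic phase at the single training orientation.

    Plasticity acts on all excitatory-presynaptic synapses (E->E and E->I)
    for ``schedule.t_plastic`` ms; the returned graph carries the final
    efficacies, frozen, ready for a measurement protocol.  Inhibitory
    efficacies are untouched (identically 1).
    """
    flat = flatten_graph(graph, rec)
    i_ext = _external_current(layout, schedule.theta_train_deg, ff, rec)
    spike_idx, spike_t, _ = run_single(
        flat,
        i_ext,
        neuron,
        rec,
        dt,
        schedule.t_plastic,
        seed,
        stdp=stdp,
        t_plastic_ms=schedule.t_plastic,
        max_rate_hz=max_rate_hz,
    )
    out = graph.copy()
    flat.write_back(out)
    return PlasticityResult(
        graph=out,
        spike_idx=spike_idx,
        spike_t=spike_t,
        theta_train_deg=schedule.theta_train_deg,
        t_plastic=schedule.t_plastic,
    )


def mean_field_dw(
    nu_post_hz: float,
    nu_pre_hz: float,
    xi_post: float,
    xi_pre: float,
    dpo_deg,
    alpha_ms: float,
):
    """Predicted mean efficacy drift per second for uncorrelated trains.

    Averaging the pair rule over the stimulus ensemble, with cosine tuning
    curves of selectivity xi and mean rates nu, gives

        dw/dt = alpha * nu_post * nu_pre * (1 + 2 xi_post xi_pre cos(2 dPO)).

    Rates in Hz, ``alpha`` (the STDP window integral) in ms, ``dpo_deg`` the
    preferred-orientation difference in degrees; result in 1/s.
    """
    for name, xi in (("xi_post", xi_post), ("xi_pre", xi_pre)):
        if not 0.0 <= xi <= 0.5:
            raise ValueError(f"{name}={xi} outside [0, 0.5]")
    dpo = np.deg2rad(np.asarray(dpo_deg, dtype=float))
    alpha_s = alpha_ms * 1e-3
    return alpha_s * nu_post_hz * nu_pre_hz * (
        1.0 + 2.0 * xi_post * xi_pre * np.cos(2.0 * dpo)
    )
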