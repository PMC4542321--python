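"""Numba integration kernel for the two-population LIF network.

The recurrent current of Eq.-form  sum_j g w C exp(-(t-t_k)/tau_syn)/tau_syn
is evaluated with two per-neuron accumulators (one per presynaptic synapse
type, since all excitatory synapses share tau_syn_E and all inhibitory ones
tau_syn_I): each accumulator decays by exp(-dt/tau_syn) per step and jumps
by g*w/tau_syn when a presynaptic spike arrives.  This is mathematically
identical to the explicit spike sum at O(N + spikes*fanout) cost.

Within-step order: (1) decay accumulators and STDP traces, (2) compute
currents from the *previous* step's spikes, (3) forward-Euler membrane
update, (4) threshold/reset, (5) apply STDP pairings against past spikes
only, (6) push this step's spikes into accumulators and traces.  Spikes
therefore act with a one-step (dt) transmission latency, and two spikes in
the same step never pair with each other (dt = 0 contributes no update).

STDP (multiplicative, all-to-all pairing) uses one presynaptic trace per
excitatory neuron (decay tau_plus) and one postsynaptic trace per neuron
(decay tau_minus); the multiplicative factors (2 - w) and w are applied with
the weight value current at the triggering spike.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_OVERFLOW = 2


@njit(cache=True)
def run_lif(
    # network shape
    n_e,
    n,
    # neuron / integration
    dt,
    n_steps,
    tau,
    r_m,
    v_t,
    v_reset,
    v,  # (n,) initial membrane potential, modified in place
    i_ext,  # (n,) constant external current, nA
    # synapses
    decay_e,
    decay_i,
    out_ptr,
    out_post,
    out_gain,
    out_widx,
    w,  # (n_plastic_edges,) efficacies, modified in place when plastic
    in_ptr,
    in_pre,
    in_widx,
    # plasticity
    plastic_steps,  # 0 disables STDP entirely
    a_plus,
    a_minus,
    decay_plus,
    decay_minus,
    w_max,
    # outputs
    spike_n,  # (cap,) int32
    spike_t,  # (cap,) float64
    probe_idx,  # -1 disables the current probe
    probe_exc,  # (n_steps,) or (0,)
    probe_inh,
):
    x_e = np.zeros(n)
    x_i = np.zeros(n)
    x_pre = np.zeros(n_e)
    y_post = np.zeros(n)
    spiked = np.empty(n, dtype=np.int64)
    cap = spike_n.shape[0]
    n_spikes = 0
    stdp_on = plastic_steps > 0
    euler = dt / tau

    for step in range(n_steps):
        plastic = step < plastic_steps
        if stdp_on:
            for j in range(n_e):
                x_pre[j] *= decay_plus
            for i in range(n):
                y_post[i] *= decay_minus

        nsp = 0
        for i in range(n):
            xe = x_e[i] * decay_e
            xi = x_i[i] * decay_i
            x_e[i] = xe
            x_i[i] = xi
            vi = v[i] + euler * (-v[i] + r_m * (i_ext[i] + xe - xi))
            if vi >= v_t:
                spiked[nsp] = i
                nsp += 1
                vi = v_reset
            v[i] = vi

        if probe_idx >= 0:
            probe_exc[step] = i_ext[probe_idx] + x_e[probe_idx]
            probe_inh[step] = x_i[probe_idx]

        if (step & 127) == 0:
            for i in range(n):
                if not np.isfinite(v[i]):
                    return n_spikes, STATUS_NONFINITE, step, i

        if plastic and nsp > 0:
            # all potentiation passes first, then all depression passes, so
            # the event order within a step is fixed (and dt=0 pairs are
            # excluded because traces are updated only in phase 6 below)
            for s in range(nsp):
                i = spiked[s]
                # post spike: potentiate against all earlier pre spikes
                for e in range(in_ptr[i], in_ptr[i + 1]):
                    widx = in_widx[e]
                    wv = w[widx]
                    wv += a_plus * x_pre[in_pre[e]] * (w_max - wv)
                    if wv < 0.0:
                        wv = 0.0
                    elif wv > w_max:
                        wv = w_max
                    w[widx] = wv
            for s in range(nsp):
                i = spiked[s]
                # pre spike (excitatory only): depress against earlier post spikes
                if i < n_e:
                    for e in range(out_ptr[i], out_ptr[i + 1]):
                        widx = out_widx[e]
                        wv = w[widx]
                        wv += a_minus * y_post[out_post[e]] * wv
                        if wv < 0.0:
                            wv = 0.0
                        elif wv > w_max:
                            wv = w_max
                        w[widx] = wv

        if nsp > 0:
            t_spike = (step + 1) * dt
            if n_spikes + nsp > cap:
                return n_spikes, STATUS_OVERFLOW, step, -1
            for s in range(nsp):
                j = spiked[s]
                spike_n[n_spikes] = j
                spike_t[n_spikes] = t_spike
                n_spikes += 1
                if j < n_e:
                    for e in range(out_ptr[j], out_ptr[j + 1]):
                        x_e[out_post[e]] += out_gain[e] * w[out_widx[e]]
                    if stdp_on:
                        x_pre[j] += 1.0
                else:
                    for e in range(out_ptr[j], out_ptr[j + 1]):
                        x_i[out_post[e]] += out_gain[e]
                if stdp_on:
                    y_post[j] += 1.0

    return n_spikes, STATUS_OK, n_steps, -1
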