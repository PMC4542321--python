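"""Spiking simulation of the balanced two-population network.

Feed-forward and background drives are deterministic constant currents; all
temporal variability is generated by the recurrent balanced dynamics.  Runs
are reproducible: the per-angle seed is derived from the master seed and the
angle index, and only the initial membrane potentials are random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .connectivity import ConnectivityGraph
from .geometry import OrientationLayout
from .params import (
    FeedforwardParams,
    NeuronParams,
    RecurrentParams,
    SimProtocol,
    STDPParams,
)

__all__ = [
    "FlatNetwork",
    "SpikeData",
    "ProbeTrace",
    "SimulationError",
    "feedforward_current",
    "background_current",
    "flatten_graph",
    "run_single",
    "run_protocol",
]


class SimulationError(RuntimeError):
    pass


def feedforward_current(
    theta: np.ndarray,
    theta_stim: float,
    ff: FeedforwardParams,
    pop: str = "E",
    k: float | None = None,
) -> np.ndarray:
    """Constant layer-4 drive (nA) for neurons with preferred angles ``theta``.

    ``theta`` and ``theta_stim`` in radians.  With ``k`` given and
    ``ff.ff_ref_k`` set, the drive scales as sqrt(k / ff_ref_k) so that
    in-degree sweeps keep the balanced sqrt(K) input scaling; at the default
    K the factor is 1.
    """
    base = ff.g_al * ff.k_al * (ff.fr_l / 1000.0)
    if k is not None and ff.ff_ref_k is not None:
        base *= np.sqrt(k / ff.ff_ref_k)
    rho = ff.rho(pop)
    return base * (1.0 + 2.0 * rho * np.cos(2.0 * (theta_stim - np.asarray(theta))))


def background_current(rec: RecurrentParams, pop: str = "E") -> float:
    """sqrt(K) * I_back_A: the net drive of K weak excitatory inputs (nA)."""
    i_back = rec.i_back_e if pop == "E" else rec.i_back_i
    return np.sqrt(rec.k) * i_back


@dataclass
class FlatNetwork:
    """Edge-list arrays consumed by the integration kernel.

    Plastic (excitatory-presynaptic) efficacies live in ``w`` in a canonical
    order: all E->E edges in CSR (postsynaptic-major) order, then all E->I
    edges.  ``out_*`` index every edge by presynaptic neuron for spike
    propagation; ``in_*`` index the plastic edges by postsynaptic neuron for
    the STDP potentiation pass.
    """

    n_e: int
    n_i: int
    out_ptr: np.ndarray = field(repr=False)
    out_post: np.ndarray = field(repr=False)
    out_gain: np.ndarray = field(repr=False)
    out_widx: np.ndarray = field(repr=False)
    in_ptr: np.ndarray = field(repr=False)
    in_pre: np.ndarray = field(repr=False)
    in_widx: np.ndarray = field(repr=False)
    w: np.ndarray = field(repr=False)
    n_ee: int = 0

    @property
    def n(self) -> int:
        return self.n_e + self.n_i

    def write_back(self, graph: ConnectivityGraph) -> None:
        """Copy current efficacies into the graph's sparse blocks."""
        graph.blocks[("E", "E")].data[:] = self.w[: self.n_ee]
        graph.blocks[("I", "E")].data[:] = self.w[self.n_ee :]


def flatten_graph(graph: ConnectivityGraph, rec: RecurrentParams) -> FlatNetwork:
    n_e, n_i = graph.geom.n_e, graph.geom.n_i
    n = n_e + n_i
    tau_syn = {"E": rec.tau_syn_e, "I": rec.tau_syn_i}
    offset = {"E": 0, "I": n_e}

    ee = graph.blocks[("E", "E")].tocsr()
    ie = graph.blocks[("I", "E")].tocsr()
    n_ee = ee.nnz
    w = np.concatenate([ee.data.astype(float), ie.data.astype(float)])

    # plastic in-edges per postsynaptic neuron (all presynaptic E)
    in_ptr = np.concatenate([ee.indptr[:-1], n_ee + ie.indptr]).astype(np.int64)
    in_pre = np.concatenate([ee.indices, ie.indices]).astype(np.int64)
    in_widx = np.arange(n_ee + ie.nnz, dtype=np.int64)

    # out-edges per presynaptic neuron, across all four blocks
    pre_l, post_l, gain_l, widx_l = [], [], [], []
    widx_base = {("E", "E"): 0, ("I", "E"): n_ee}
    for (post, pre), block in graph.blocks.items():
        csr = block.tocsr()
        rows = np.repeat(np.arange(csr.shape[0]), np.diff(csr.indptr))
        gain = abs(rec.g_scaled(post, pre)) / tau_syn[pre]
        pre_l.append(csr.indices + offset[pre])
        post_l.append(rows + offset[post])
        gain_l.append(np.full(csr.nnz, gain))
        if pre == "E":
            widx_l.append(widx_base[(post, pre)] + np.arange(csr.nnz))
        else:
            widx_l.append(np.full(csr.nnz, -1, dtype=np.int64))
    pre_all = np.concatenate(pre_l)
    order = np.argsort(pre_all, kind="stable")
    pre_all = pre_all[order]
    out_post = np.concatenate(post_l)[order].astype(np.int64)
    out_gain = np.concatenate(gain_l)[order]
    out_widx = np.concatenate(widx_l)[order].astype(np.int64)
    out_ptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(out_ptr, pre_all + 1, 1)
    out_ptr = np.cumsum(out_ptr)

    return FlatNetwork(
        n_e=n_e,
        n_i=n_i,
        out_ptr=out_ptr,
        out_post=out_post,
        out_gain=out_gain,
        out_widx=out_widx,
        in_ptr=in_ptr,
        in_pre=in_pre,
        in_widx=in_widx,
        w=w,
        n_ee=n_ee,
    )


@dataclass
class ProbeTrace:
    """Per-step input components of one probed neuron, in nA."""

    neuron: int
    dt: float
    exc: np.ndarray = field(repr=False)  # feed-forward + recurrent E + background
    inh: np.ndarray = field(repr=False)  # magnitude of the recurrent I component


@dataclass
class SpikeData:
    """Spike rasters grouped by stimulus angle (degrees).

    ``spikes[angle] = (neuron_index, time_ms)``; global neuron indices with
    excitatory neurons first.  Times are step-quantized and lie in
    ``(0, t_total]``; spikes before ``t_transient`` are retained here and
    excluded by the rate estimators.
    """

    n_e: int
    n_i: int
    t_total: float
    t_transient: float
    spikes: dict = field(repr=False, default_factory=dict)
    probes: dict = field(repr=False, default_factory=dict)

    @property
    def angles_deg(self) -> list:
        return sorted(self.spikes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for angle, (idx, t) in sorted(self.spikes.items()):
            pop = np.where(idx < self.n_e, "E", "I")
            local = np.where(idx < self.n_e, idx, idx - self.n_e)
            rows.append(
                pd.DataFrame(
                    {"angle_deg": angle, "population": pop, "neuron": local, "time_ms": t}
                )
            )
        return pd.concat(rows, ignore_index=True)


def _external_current(
    layout: OrientationLayout,
    theta_stim_deg: float,
    ff: FeedforwardParams,
    rec: RecurrentParams,
) -> np.ndarray:
    th = np.deg2rad(theta_stim_deg)
    i_e = feedforward_current(layout.theta_e, th, ff, "E", k=rec.k) + background_current(rec, "E")
    i_i = feedforward_current(layout.theta_i, th, ff, "I", k=rec.k) + background_current(rec, "I")
    return np.concatenate([i_e, i_i])


def run_single(
    flat: FlatNetwork,
    i_ext: np.ndarray,
    neuron: NeuronParams,
    rec: RecurrentParams,
    dt: float,
    t_ms: float,
    seed,
    stdp: STDPParams | None = None,
    t_plastic_ms: float = 0.0,
    probe: int | None = None,
    max_rate_hz: float = 250.0,
):
    """Integrate one run; returns (spike_idx, spike_t_ms, probe or None).

    Modifies ``flat.w`` in place when ``stdp`` is given with a positive
    plastic window.  Initial membrane potentials are uniform on
    [v_reset, v_t) from ``seed`` to avoid artificial synchrony.
    """
    n = flat.n
    n_steps = int(round(t_ms / dt))
    rng = np.random.default_rng(seed)
    v = rng.uniform(neuron.v_reset, neuron.v_t, n)
    cap = max(int(n * (t_ms / 1000.0) * max_rate_hz), 10_000)
    spike_n = np.empty(cap, dtype=np.int32)
    spike_t = np.empty(cap, dtype=np.float64)
    probe_idx = -1 if probe is None else int(probe)
    if probe is not None and not 0 <= probe_idx < n:
        raise ValueError(f"probe neuron {probe} outside the simulated range [0, {n})")
    probe_exc = np.zeros(n_steps if probe is not None else 0)
    probe_inh = np.zeros_like(probe_exc)
    p = stdp if stdp is not None else STDPParams()
    plastic_steps = int(round(t_plastic_ms / dt)) if stdp is not None else 0

    n_spikes, status, err_step, err_neuron = _kernel.run_lif(
        flat.n_e,
        n,
        dt,
        n_steps,
        neuron.tau,
        neuron.r_m,
        neuron.v_t,
        neuron.v_reset,
        v,
        np.ascontiguousarray(i_ext, dtype=float),
        np.exp(-dt / rec.tau_syn_e),
        np.exp(-dt / rec.tau_syn_i),
        flat.out_ptr,
        flat.out_post,
        flat.out_gain,
        flat.out_widx,
        flat.w,
        flat.in_ptr,
        flat.in_pre,
        flat.in_widx,
        plastic_steps,
        p.a_plus,
        p.a_minus,
        np.exp(-dt / p.tau_plus),
        np.exp(-dt / p.tau_minus),
        p.w_max,
        spike_n,
        spike_t,
        probe_idx,
        probe_exc,
        probe_inh,
    )
    if status == _kernel.STATUS_NONFINITE:
        raise SimulationError(
            f"non-finite membrane potential at t={err_step * dt:.3f} ms, "
            f"neuron {err_neuron}"
        )
    if status == _kernel.STATUS_OVERFLOW:
        raise SimulationError(
            f"spike buffer overflow at t={err_step * dt:.3f} ms; "
            f"raise max_rate_hz (currently {max_rate_hz})"
        )
    trace = None
    if probe is not None:
        trace = ProbeTrace(neuron=probe_idx, dt=dt, exc=probe_exc, inh=probe_inh)
    return spike_n[:n_spikes].copy(), spike_t[:n_spikes].copy(), trace


def angle_seed(master_seed: int, angle_index: int) -> np.random.SeedSequence:
    """Deterministic per-angle seed derived from the master seed."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(angle_index,))


def run_protocol(
    graph: ConnectivityGraph,
    layout: OrientationLayout,
    neuron: NeuronParams,
    ff: FeedforwardParams,
    rec: RecurrentParams,
    protocol: SimProtocol,
    probe: int | None = None,
) -> SpikeData:
    """One independent frozen-weight run per stimulus angle."""
    flat = flatten_graph(graph, rec)
    data = SpikeData(
        n_e=graph.geom.n_e,
        n_i=graph.geom.n_i,
        t_total=protocol.t_total,
        t_transient=protocol.t_transient,
    )
    for idx, angle in enumerate(protocol.angles_deg):
        i_ext = _external_current(layout, angle, ff, rec)
        w_before = flat.w.copy()
        spike_n, spike_t, trace = run_single(
            flat,
            i_ext,
            neuron,
            rec,
            protocol.dt,
            protocol.t_total,
            angle_seed(protocol.seed, idx),
            probe=probe,
            max_rate_hz=protocol.max_rate_hz,
        )
        flat.w = w_before  # frozen-weight protocol: no carry-over between angles
        data.spikes[float(angle)] = (spike_n, spike_t)
        if trace is not None:
            data.probes[float(angle)] = trace
    return data
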