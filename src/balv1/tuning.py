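"""Tuning curves, selectivity indices, and functional-connectivity summaries.

The orientation selectivity index (OSI) is the ratio of the first to the
zeroth circular Fourier component of the firing rate over the stimulus set,

    OSI = sqrt[(sum_t f cos 2t)^2 + (sum_t f sin 2t)^2] / sum_t f,

0 for flat tuning and 1 for a delta-function curve.  The preferred
orientation (PO) is the population-vector angle, atan2 of the same sums
halved, mapped to [0, 180) degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityGraph
from .params import NeuronParams
from .simulate import ProbeTrace, SpikeData

__all__ = [
    "TuningResult",
    "CosineFit",
    "firing_rates",
    "osi",
    "preferred_orientation",
    "measure_tuning",
    "population_summary",
    "bin_and_fit_dw",
    "input_decomposition",
    "circular_correlation",
    "isi_cv",
]


@dataclass
class TuningResult:
    """Per-neuron rates (Hz) per stimulus angle, OSI, and PO (deg)."""

    angles_deg: np.ndarray
    rates: np.ndarray = field(repr=False)  # (n_neurons, n_angles)
    osi: np.ndarray = field(repr=False)
    po_deg: np.ndarray = field(repr=False)  # NaN where the neuron is silent
    n_e: int = 0

    def pop_slice(self, pop: str) -> slice:
        return slice(0, self.n_e) if pop == "E" else slice(self.n_e, None)


def firing_rates(spikes: SpikeData, window: tuple[float, float] | None = None) -> np.ndarray:
    """Spike count in the half-open window [t_start, t_end), in Hz.

    Defaults to [t_transient, t_total), discarding the settling transient.
    Returns an (n_neurons, n_angles) array, angles sorted ascending.
    """
    if window is None:
        window = (spikes.t_transient, spikes.t_total)
    t0, t1 = window
    if t0 < spikes.t_transient:
        raise ValueError("window starts inside the discarded transient")
    if not t1 > t0:
        raise ValueError("empty spike-counting window")
    n = spikes.n_e + spikes.n_i
    angles = spikes.angles_deg
    rates = np.zeros((n, len(angles)))
    for a, angle in enumerate(angles):
        idx, t = spikes.spikes[angle]
        keep = (t >= t0) & (t < t1)
        counts = np.bincount(idx[keep], minlength=n)
        rates[:, a] = counts / (t1 - t0) * 1000.0
    return rates


def _tuning_vector(rates: np.ndarray, angles_deg) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    th = 2.0 * np.deg2rad(np.asarray(angles_deg, dtype=float))
    rates = np.atleast_2d(rates)
    c = rates @ np.cos(th)
    s = rates @ np.sin(th)
    f0 = rates.sum(axis=1)
    return c, s, f0


def osi(rates: np.ndarray, angles_deg) -> np.ndarray:
    """Orientation selectivity index per neuron; NaN where sum of rates is 0."""
    c, s, f0 = _tuning_vector(rates, angles_deg)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.hypot(c, s) / f0
    return np.where(f0 > 0, out, np.nan)


def preferred_orientation(rates: np.ndarray, angles_deg) -> np.ndarray:
    """Population-vector preferred orientation, degrees in [0, 180); NaN if silent."""
    c, s, f0 = _tuning_vector(rates, angles_deg)
    po = np.mod(np.rad2deg(0.5 * np.arctan2(s, c)), 180.0)
    return np.where(f0 > 0, po, np.nan)


def measure_tuning(spikes: SpikeData, window=None) -> TuningResult:
    rates = firing_rates(spikes, window)
    angles = np.asarray(spikes.angles_deg, dtype=float)
    return TuningResult(
        angles_deg=angles,
        rates=rates,
        osi=osi(rates, angles),
        po_deg=preferred_orientation(rates, angles),
        n_e=spikes.n_e,
    )


def population_summary(
    tuning: TuningResult, include_silent: bool = False, bins: int = 20
) -> pd.DataFrame:
    """Per-population mean OSI, mean rate, silent count, and OSI histogram.

    Silent neurons (zero total rate, undefined OSI) are excluded from the
    OSI mean unless ``include_silent`` maps them to 0.
    """
    rows = []
    for pop in ("E", "I"):
        sl = tuning.pop_slice(pop)
        o = tuning.osi[sl]
        silent = np.isnan(o)
        vals = np.where(silent, 0.0, o) if include_silent else o[~silent]
        hist, _ = np.histogram(vals[np.isfinite(vals)], bins=bins, range=(0.0, 1.0))
        rows.append(
            {
                "population": pop,
                "n": o.size,
                "n_silent": int(silent.sum()),
                "mean_osi": float(np.mean(vals)) if vals.size else np.nan,
                "mean_rate_hz": float(tuning.rates[sl].mean(axis=1).mean()),
                "osi_hist": hist,
            }
        )
    return pd.DataFrame(rows).set_index("population")


@dataclass
class CosineFit:
    """Least-squares fit a0 + 2 a1 cos(pi x / 90) to 10-deg-binned means."""

    a0: float
    a1: float
    bin_centers: np.ndarray = field(repr=False)
    bin_means: np.ndarray = field(repr=False)
    bin_counts: np.ndarray = field(repr=False)
    residual: float = 0.0

    def predict(self, x_deg) -> np.ndarray:
        return self.a0 + 2.0 * self.a1 * np.cos(np.pi * np.asarray(x_deg) / 90.0)


def fit_cosine_bins(x_deg: np.ndarray, y: np.ndarray, counts=None) -> CosineFit:
    """Unweighted least squares of a0 + 2 a1 cos(pi x/90) on bin means."""
    x_deg = np.asarray(x_deg, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones_like(x_deg), 2.0 * np.cos(np.pi * x_deg / 90.0)])
    coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = float(res[0]) if np.size(res) else 0.0
    return CosineFit(
        a0=float(coef[0]),
        a1=float(coef[1]),
        bin_centers=x_deg,
        bin_means=y,
        bin_counts=np.asarray(counts) if counts is not None else np.ones_like(y),
        residual=resid,
    )


def bin_and_fit_dw(
    graph: ConnectivityGraph,
    po_e_deg: np.ndarray,
    bin_width_deg: float = 10.0,
    reference: float = 0.0,
) -> CosineFit:
    """Mean E->E efficacy (minus ``reference``) vs wrapped PO difference.

    For every E->E edge, compute the wrapped |PO_post - PO_pre| in [0, 90]
    (double-angle metric), average ``w - reference`` in ``bin_width_deg``
    bins, and fit the two-parameter cosine.  ``reference=1`` turns the fit
    into the net efficacy change of a plasticity run.
    """
    block = graph.blocks[("E", "E")].tocoo()
    dpo = np.abs(
        0.5
        * np.rad2deg(
            np.angle(np.exp(2j * np.deg2rad(po_e_deg[block.row] - po_e_deg[block.col])))
        )
    )
    w = block.data - reference
    n_bins = int(round(90.0 / bin_width_deg))
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    which = np.clip(np.digitize(dpo, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=w, minlength=n_bins)
    keep = counts > 0
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} empty orientation-difference bins excluded")
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        means = sums[keep] / counts[keep]
    return fit_cosine_bins(centers[keep], means, counts[keep])


def input_decomposition(trace: ProbeTrace, neuron: NeuronParams) -> pd.DataFrame:
    """Excitatory / inhibitory / net input components of a probed neuron, mV.

    The excitatory component bundles feed-forward, recurrent-excitatory, and
    background drive; the inhibitory component is the recurrent inhibition
    (shown as a negative contribution); both are scaled by R_m.
    """
    exc = neuron.r_m * trace.exc
    inh = -neuron.r_m * trace.inh
    return pd.DataFrame(
        {
            "time_ms": (np.arange(exc.size) + 1) * trace.dt,
            "exc_mv": exc,
            "inh_mv": inh,
            "net_mv": exc + inh,
        }
    )


def circular_correlation(a_deg: np.ndarray, b_deg: np.ndarray) -> float:
    """Fisher-Lee circular correlation of two orientation samples (degrees).

    Angles are doubled to map the [0, 180) orientation domain onto the
    circle.  Computed via the O(N) expansion of the pairwise sine products.
    """
    a = 2.0 * np.deg2rad(np.asarray(a_deg, dtype=float))
    b = 2.0 * np.deg2rad(np.asarray(b_deg, dtype=float))
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    sa, ca, sb, cb = np.sin(a), np.cos(a), np.sin(b), np.cos(b)
    num = (sa * sb).sum() * (ca * cb).sum() - (sa * cb).sum() * (ca * sb).sum()
    den_a = (sa * sa).sum() * (ca * ca).sum() - ((sa * ca).sum()) ** 2
    den_b = (sb * sb).sum() * (cb * cb).sum() - ((sb * cb).sum()) ** 2
    return float(num / np.sqrt(den_a * den_b))


def isi_cv(spikes: SpikeData, angle: float | None = None, min_spikes: int = 5) -> np.ndarray:
    """Interspike-interval coefficient of variation per neuron.

    Uses spikes after the transient of one stimulus angle (the first by
    default); neurons with fewer than ``min_spikes`` spikes give NaN.
    CV well above zero (>~0.5) is the signature of irregular,
    fluctuation-driven firing in the balanced state.
    """
    if angle is None:
        angle = spikes.angles_deg[0]
    idx, t = spikes.spikes[angle]
    keep = t >= spikes.t_transient
    idx, t = idx[keep], t[keep]
    n = spikes.n_e + spikes.n_i
    out = np.full(n, np.nan)
    order = np.lexsort((t, idx))
    idx, t = idx[order], t[order]
    bounds = np.searchsorted(idx, np.arange(n + 1))
    for i in range(n):
        ti = t[bounds[i] : bounds[i + 1]]
        if ti.size >= min_spikes:
            isi = np.diff(ti)
            m = isi.mean()
            if m > 0:
                out[i] = isi.std(ddof=0) / m
    return out
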