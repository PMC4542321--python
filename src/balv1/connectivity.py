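"""Distance-dependent random connectivity and the reconnection rule.

Connections from presynaptic neuron ``(j, B)`` to postsynaptic neuron
``(i, A)`` are independent Bernoulli draws with probability

    p_iA,jB = Z_AB * G(x_i - x_j, sigma) * G(y_i - y_j, sigma),

where ``G`` is an ``M``-periodic Gaussian and ``Z_AB`` normalizes the
expected in-degree to ``K`` for every postsynaptic neuron.  Normalized
efficacies start at ``w = 1``; inhibitory-presynaptic efficacies stay 1
forever (only excitatory synapses are plastic).

The reconnection rule resamples the whole graph with the base probability
modulated by the cosine of twice the preferred-orientation difference,
``p * (1 + eps_cB * cos(2 (PO_j - PO_i)))`` — functional connectivity whose
strength depends only on the presynaptic population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .geometry import LayerGeometry

__all__ = [
    "ConnectivityParams",
    "ReconnectionParams",
    "ConnectivityGraph",
    "periodic_gaussian",
    "sample_connectivity",
    "reconnect",
]

_PAIRS = [("E", "E"), ("E", "I"), ("I", "E"), ("I", "I")]
_CHUNK = 512  # postsynaptic rows sampled per block, bounds peak memory


@dataclass(frozen=True)
class ConnectivityParams:
    """Target mean in-degree and Gaussian footprint of the recurrent graph."""

    k: float = 500.0
    sigma: float = 0.2  # in units of M
    k_max: int = 5  # periodic-sum truncation; remainder < e^-300 at sigma=0.2M


@dataclass(frozen=True)
class ReconnectionParams:
    """Presynaptic-population reconnection modulations, each in [0, 1]."""

    eps_ce: float = 0.0
    eps_ci: float = 0.0

    def __post_init__(self):
        for name, v in (("eps_ce", self.eps_ce), ("eps_ci", self.eps_ci)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def eps(self, pre: str) -> float:
        return self.eps_ce if pre == "E" else self.eps_ci


@dataclass
class ConnectivityGraph:
    """Sparse adjacency per ordered population pair, weights on E-presynaptic edges.

    ``blocks[(A, B)]`` is a CSR matrix of shape (N_A, N_B) for direction
    B -> A; its ``data`` holds the normalized efficacies ``w`` (identically 1
    for inhibitory presynaptic blocks).
    """

    geom: LayerGeometry
    params: ConnectivityParams
    blocks: dict[tuple[str, str], sparse.csr_matrix] = field(repr=False)
    seed: int | None = None
    reconnection: ReconnectionParams | None = None
    clamp_count: int = 0

    def in_degrees(self, post: str, pre: str) -> np.ndarray:
        block = self.blocks[(post, pre)]
        return np.diff(block.indptr)

    def weights(self, post: str, pre: str) -> np.ndarray:
        return self.blocks[(post, pre)].data

    def copy(self) -> "ConnectivityGraph":
        return ConnectivityGraph(
            geom=self.geom,
            params=self.params,
            blocks={k: v.copy() for k, v in self.blocks.items()},
            seed=self.seed,
            reconnection=self.reconnection,
            clamp_count=self.clamp_count,
        )


def periodic_gaussian(
    x: np.ndarray | float, sigma: float, m: float, k_max: int = 5
) -> np.ndarray | float:
    """M-periodic Gaussian: sum_{k=-k_max..k_max} exp(-(x - M k)^2 / (2 sigma^2)).

    Unnormalized (value 1 + tails at x=0).  Even in ``x`` and exactly
    ``M``-periodic by construction.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    x = np.asarray(x, dtype=float)
    ks = np.arange(-k_max, k_max + 1)
    return np.exp(-((x[..., None] - m * ks) ** 2) / (2.0 * sigma**2)).sum(axis=-1)


def _axis_table(
    geom: LayerGeometry, post: str, pre: str, params: ConnectivityParams
) -> np.ndarray:
    """G over the distinct axis coordinates of the two grids, (side_A, side_B).

    Grid positions take only sqrt(N) distinct values per axis, so the
    periodic Gaussian is evaluated once on this small table and gathered,
    never recomputed per neuron pair.  The same table serves both axes.
    """
    sig = params.sigma * geom.m
    side_post = int(round(np.sqrt(geom.counts()[post])))
    side_pre = int(round(np.sqrt(geom.counts()[pre])))
    ax_post = np.arange(side_post) * geom.m / side_post
    ax_pre = np.arange(side_pre) * geom.m / side_pre
    return periodic_gaussian(ax_post[:, None] - ax_pre[None, :], sig, geom.m, params.k_max)


def _row_normalizers(
    geom: LayerGeometry, post: str, pre: str, params: ConnectivityParams, table: np.ndarray
) -> np.ndarray:
    """Per-row Z such that sum_j Z * G(dx) G(dy) = K (self term excluded).

    The product kernel is separable over the presynaptic grid, so the row
    sum factorizes into one sum per axis; on the aligned grids used here the
    result is the same for every row up to float precision.
    """
    side_post = int(round(np.sqrt(geom.counts()[post])))
    axis_sum = table.sum(axis=1)
    i = np.arange(geom.counts()[post])
    total = axis_sum[i % side_post] * axis_sum[i // side_post]
    if post == pre:
        sig = params.sigma * geom.m
        total = total - periodic_gaussian(0.0, sig, geom.m, params.k_max) ** 2
    return params.k / total


def _sample_block(
    geom: LayerGeometry,
    post: str,
    pre: str,
    params: ConnectivityParams,
    rng: np.random.Generator,
    modulation: tuple[np.ndarray, np.ndarray, float] | None = None,
) -> tuple[sparse.csr_matrix, int]:
    """Bernoulli-sample one (post, pre) block; returns (csr, n_clamped).

    ``modulation=(po_post, po_pre, eps)`` applies the reconnection factor
    ``1 + eps cos(2 (PO_pre - PO_post))`` to the base probability.
    """
    n_post = geom.counts()[post]
    n_pre = geom.counts()[pre]
    if params.k > n_pre:
        raise ValueError(
            f"mean in-degree K={params.k} cannot exceed the presynaptic "
            f"population size {n_pre} ({pre}); at K = N_B the block saturates "
            "to full connectivity through probability clamping"
        )
    table = _axis_table(geom, post, pre, params)
    z = _row_normalizers(geom, post, pre, params, table)
    side_post = int(round(np.sqrt(n_post)))
    side_pre = int(round(np.sqrt(n_pre)))
    jp = np.arange(n_pre)
    jx, jy = jp % side_pre, jp // side_pre
    if modulation is not None:
        po_post, po_pre, eps = modulation
        c_pre, s_pre = np.cos(2.0 * po_pre), np.sin(2.0 * po_pre)
        c_post, s_post = np.cos(2.0 * po_post), np.sin(2.0 * po_post)
    rows, cols = [], []
    n_clamped = 0
    max_p = 0.0
    for start in range(0, n_post, _CHUNK):
        stop = min(start + _CHUNK, n_post)
        i = np.arange(start, stop)
        p = (
            z[i, None]
            * table[i % side_post][:, jx]
            * table[i // side_post][:, jy]
        )
        if modulation is not None:
            # cos(2(PO_pre - PO_post)) via the product expansion, no per-pair cos
            p = p * (
                1.0
                + eps
                * (c_post[i, None] * c_pre[None, :] + s_post[i, None] * s_pre[None, :])
            )
        if post == pre:
            idx = np.arange(start, stop)
            p[np.arange(stop - start), idx] = 0.0
        over = p > 1.0
        if over.any():
            n_clamped += int(over.sum())
            max_p = max(max_p, float(p.max()))
            np.clip(p, 0.0, 1.0, out=p)
        hit = rng.random(p.shape) < p
        r, c = np.nonzero(hit)
        rows.append(r + start)
        cols.append(c)
    if n_clamped:
        warnings.warn(
            f"{post}<-{pre}: clamped {n_clamped} connection probabilities to 1 "
            f"(max unclamped p = {max_p:.3f})",
            stacklevel=3,
        )
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    block = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_post, n_pre)
    )
    return block, n_clamped


def sample_connectivity(
    geom: LayerGeometry, params: ConnectivityParams, seed: int | None = None
) -> ConnectivityGraph:
    """Draw the four adjacency blocks; all efficacies initialized to 1."""
    rng = np.random.default_rng(seed)
    blocks = {}
    clamped = 0
    for post, pre in _PAIRS:
        blocks[(post, pre)], n = _sample_block(geom, post, pre, params, rng)
        clamped += n
    return ConnectivityGraph(
        geom=geom, params=params, blocks=blocks, seed=seed, clamp_count=clamped
    )


def reconnect(
    graph: ConnectivityGraph,
    po_e: np.ndarray,
    po_i: np.ndarray,
    rec: ReconnectionParams,
    seed: int | None = None,
) -> ConnectivityGraph:
    """Resample the whole graph with PO-modulated connection probabilities.

    ``po_e``, ``po_i`` are per-neuron preferred orientations in radians
    (measured, e.g., from a control simulation).  The modulation depends only
    on the presynaptic population; weights are reset to 1 on the fresh graph.
    When the POs are uniform the expected in-degree is preserved (the cosine
    averages to zero).
    """
    if po_e.shape[0] != graph.geom.n_e or po_i.shape[0] != graph.geom.n_i:
        raise ValueError("need one preferred orientation per neuron in each population")
    po = {"E": np.asarray(po_e, dtype=float), "I": np.asarray(po_i, dtype=float)}
    rng = np.random.default_rng(seed)
    blocks = {}
    clamped = 0
    for post, pre in _PAIRS:
        blocks[(post, pre)], n = _sample_block(
            graph.geom,
            post,
            pre,
            graph.params,
            rng,
            modulation=(po[post], po[pre], rec.eps(pre)),
        )
        clamped += n
    return ConnectivityGraph(
        geom=graph.geom,
        params=graph.params,
        blocks=blocks,
        seed=seed,
        reconnection=rec,
        clamp_count=clamped,
    )
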