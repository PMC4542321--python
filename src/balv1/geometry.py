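"""Patch geometry and orientation layouts.

The model cortex is a square patch of side ``M`` (nominally 1 mm) with the
excitatory and inhibitory populations each arranged on their own regular
square grid.  Every neuron carries a preferred feed-forward orientation in
``[0, pi)``; the layout is either a smooth pinwheel *orientation map* (the
cat/monkey scenario) or an i.i.d. uniform *salt-and-pepper* assignment (the
rodent scenario).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LayerGeometry",
    "OrientationLayout",
    "build_geometry",
    "orientation_map",
    "assign_orientations",
    "wrap_orientation",
    "orientation_difference",
]


@dataclass(frozen=True)
class LayerGeometry:
    """Grid positions of both populations inside the ``[0, M)^2`` patch."""

    m: float
    n_e: int
    n_i: int
    pos_e: np.ndarray = field(repr=False)  # (N_E, 2)
    pos_i: np.ndarray = field(repr=False)  # (N_I, 2)

    def positions(self, pop: str) -> np.ndarray:
        return self.pos_e if pop == "E" else self.pos_i

    def counts(self) -> dict[str, int]:
        return {"E": self.n_e, "I": self.n_i}


@dataclass(frozen=True)
class OrientationLayout:
    """Per-neuron preferred feed-forward orientation, radians in ``[0, pi)``."""

    mode: str  # "map" | "random"
    theta_e: np.ndarray = field(repr=False)
    theta_i: np.ndarray = field(repr=False)

    def theta(self, pop: str) -> np.ndarray:
        return self.theta_e if pop == "E" else self.theta_i


def _grid_positions(n: int, m: float) -> np.ndarray:
    side = int(round(np.sqrt(n)))
    if side * side != n:
        raise ValueError(f"population size {n} is not a perfect square")
    i = np.arange(n)
    ix = i % side
    iy = i // side
    return np.column_stack((ix * m / side, iy * m / side))


def build_geometry(n_e: int, n_i: int, m: float = 1.0) -> LayerGeometry:
    """Place ``n_e`` excitatory and ``n_i`` inhibitory neurons on square grids.

    Neuron ``i`` (0-based) of a population with side ``s = sqrt(N)`` sits at
    ``x = (i mod s) * M/s``, ``y = floor(i/s) * M/s``.  Deterministic.
    """
    if m <= 0:
        raise ValueError("patch size M must be positive")
    for name, n in (("excitatory", n_e), ("inhibitory", n_i)):
        side = int(round(np.sqrt(n)))
        if side * side != n:
            raise ValueError(
                f"{name} population size {n} must be a perfect square "
                "so the neurons fill a regular grid"
            )
    return LayerGeometry(
        m=m,
        n_e=n_e,
        n_i=n_i,
        pos_e=_grid_positions(n_e, m),
        pos_i=_grid_positions(n_i, m),
    )


def wrap_orientation(theta: np.ndarray | float) -> np.ndarray | float:
    """Reduce an orientation (radians) to the fundamental domain ``[0, pi)``."""
    w = np.mod(theta, np.pi)
    # guard the half-open interval against rounding (tiny negative inputs)
    return np.where(w >= np.pi, 0.0, w) if np.ndim(w) else (0.0 if w >= np.pi else w)


def orientation_map(x: np.ndarray, y: np.ndarray, m: float) -> np.ndarray:
    """Smooth pinwheel orientation map with periodic boundary conditions.

    theta(x, y) = arctan( sin(2 pi y / M) / sin(2 pi x / M) ) / 2
                  + pi/2 + pi * (1 + sign(x/M - 1/2)) / 4,   reduced mod pi.

    The map is continuous across the periodic boundaries except at its
    pinwheel singularities; the half-domain sign term stitches the two
    arctan branches together.
    """
    sx = np.sin(2 * np.pi * np.asarray(x, dtype=float) / m)
    sy = np.sin(2 * np.pi * np.asarray(y, dtype=float) / m)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sy / sx
    # 0/0 at the four lattice points where both sines vanish: pick the
    # arctan(0) branch there (any value is admissible at a singularity).
    ratio = np.where(np.isnan(ratio), 0.0, ratio)
    # exactly at x = M/2 the sign term is ambiguous; sin(2 pi x / M)
    # evaluates to +eps there, so the x < M/2 branch keeps theta continuous
    half_sign = np.where(np.asarray(x, dtype=float) / m - 0.5 > 0, 1.0, -1.0)
    theta = 0.5 * np.arctan(ratio) + np.pi / 2 + np.pi * (1.0 + half_sign) / 4.0
    return wrap_orientation(theta)


def assign_orientations(
    geom: LayerGeometry, mode: str, seed: int | None = None
) -> OrientationLayout:
    """Assign preferred feed-forward orientations to every neuron.

    ``mode="map"`` evaluates the pinwheel map at each grid position and is
    seed-independent; ``mode="random"`` draws i.i.d. uniform angles on
    ``[0, pi)`` (salt-and-pepper), reproducible from ``seed``.
    """
    if mode == "map":
        return OrientationLayout(
            mode="map",
            theta_e=orientation_map(geom.pos_e[:, 0], geom.pos_e[:, 1], geom.m),
            theta_i=orientation_map(geom.pos_i[:, 0], geom.pos_i[:, 1], geom.m),
        )
    if mode == "random":
        rng = np.random.default_rng(seed)
        return OrientationLayout(
            mode="random",
            theta_e=rng.uniform(0.0, np.pi, geom.n_e),
            theta_i=rng.uniform(0.0, np.pi, geom.n_i),
        )
    raise ValueError(f"unknown layout mode {mode!r}; expected 'map' or 'random'")


def orientation_difference(
    a: np.ndarray | float, b: np.ndarray | float, degrees: bool = False
) -> np.ndarray | float:
    """Wrapped absolute orientation difference via the double-angle metric.

    Orientations live on a half-circle, so the distance between ``a`` and
    ``b`` is ``|angle(exp(2i(a-b)))| / 2``, in ``[0, pi/2]`` (or degrees in
    ``[0, 90]``).
    """
    if degrees:
        a = np.deg2rad(a)
        b = np.deg2rad(b)
    d = 0.5 * np.abs(np.angle(np.exp(2j * (np.asarray(a) - np.asarray(b)))))
    return np.rad2deg(d) if degrees else d
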