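"""Analytic mean-field treatment of the one-dimensional ring network.

Two populations of neurons live on the unit circle of *state space*; the
coordinate theta in (0, 1] is the preferred orientation divided by pi.
Connection probabilities depend only on the state-space distance through a
normalized profile ``C_B(theta - psi)`` of the presynaptic population B, and
couplings scale as ``G_AB / sqrt(K)``.  In the large-K balanced state, the
O(sqrt(K)) inputs must cancel mode by mode, which yields a 2x2 linear system
per circular Fourier mode for the rate components ``nu_A(n)``:

    J_AE(n) nu_E(n) - J_AI(n) nu_I(n) + I_ext_A(n) = 0,   A = E, I,

with ``J_AB(n) = G_AB * C_B(n)`` (couplings held as magnitudes; the E/I sign
structure is applied internally).  The external drive has modes 0 and 1 only
(``I(0) = I_A``, ``I(1) = rho I_A``), so the rate profiles inherit modes
0 and 1 only, and the selectivity of the activity is

    nu_A(1)/nu_A(0) = rho * J_B(0)/J_B(1),

inversely proportional to the modulation of the recurrent profile.  The
fixed point is stable iff for every mode the trace/determinant conditions
``J_EE(n) - J_II(n) < 0`` and ``J_IE(n) J_EI(n) - J_EE(n) J_II(n) > 0``
hold, and feasible (positive rates) iff
``I_E/I_I > J_EI(0)/J_II(0) > J_EE(0)/J_IE(0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RingSpec",
    "BalancedSolution",
    "StabilityReport",
    "BalancedStateError",
    "cosine_profile",
    "flat_profile",
    "profile_from_function",
    "fourier_interactions",
    "balanced_rates",
    "selectivity_prediction",
    "stability_report",
    "stdp_theory",
    "STDPTheory",
]

DEFAULT_N_MAX = 8


class BalancedStateError(ValueError):
    """No feasible balanced state, or a singular Fourier mode."""


def flat_profile(n_max: int = DEFAULT_N_MAX) -> np.ndarray:
    """Salt-and-pepper in state space: no modulation, modes [1, 0, 0, ...]."""
    c = np.zeros(n_max + 1)
    c[0] = 1.0
    return c


def cosine_profile(eps: float, n_max: int = DEFAULT_N_MAX) -> np.ndarray:
    """Profile 1 + eps cos(2 pi theta): the reconnected / map-like case.

    Fourier modes (f(n) = int_0^1 f exp(-2 i pi n theta)): [1, eps/2, 0, ...].
    """
    if not 0.0 <= eps <= 1.0:
        raise ValueError("profile 1 + eps cos must stay nonnegative: eps in [0, 1]")
    c = flat_profile(n_max)
    if n_max >= 1:
        c[1] = eps / 2.0
    return c


def profile_from_function(f, n_max: int = DEFAULT_N_MAX, n_grid: int = 4096) -> np.ndarray:
    """Fourier modes of a normalized profile given as a callable on (0, 1]."""
    theta = np.arange(n_grid) / n_grid
    vals = np.asarray(f(theta), dtype=float)
    if np.any(vals < -1e-12):
        raise ValueError("connection-probability profile must be nonnegative")
    modes = np.fft.fft(vals)[: n_max + 1] / n_grid
    if abs(modes[0] - 1.0) > 1e-8:
        raise ValueError(f"profile not normalized: integral = {modes[0].real:.6f}, expected 1")
    return modes.real.copy()


@dataclass(frozen=True)
class RingSpec:
    """Couplings, drives, and presynaptic connectivity profiles of the ring.

    ``g_*`` are coupling magnitudes (the published signed values map onto
    these by dropping the sign; inhibition is subtracted internally).
    ``profile_e`` / ``profile_i`` are Fourier-mode arrays ``C_B(n)`` with
    ``C_B(0) = 1`` (normalization preserves the mean in-degree K).
    """

    g_ee: float = 32.0
    g_ei: float = 96.0
    g_ie: float = 96.0
    g_ii: float = 128.0
    i_ext_e: float = 1.0
    i_ext_i: float = 1.0
    rho: float = 0.06
    profile_e: np.ndarray = field(default_factory=flat_profile)
    profile_i: np.ndarray = field(default_factory=flat_profile)

    def __post_init__(self):
        if min(self.g_ee, self.g_ei, self.g_ie, self.g_ii) < 0:
            raise ValueError("couplings are magnitudes; use positive values")
        if not 0.0 <= self.rho <= 0.5:
            raise ValueError("input modulation rho must lie in [0, 0.5]")
        for name in ("profile_e", "profile_i"):
            prof = np.asarray(getattr(self, name), dtype=float)
            if abs(prof[0] - 1.0) > 1e-10:
                raise ValueError(f"{name} not normalized: C(0) = {prof[0]}")
            object.__setattr__(self, name, prof)

    @classmethod
    def reconnected(cls, eps_ce: float, eps_ci: float, n_max: int = DEFAULT_N_MAX, **kw):
        """Ring with cosine profiles 1 + eps_cB cos(2 pi theta) per population."""
        return cls(
            profile_e=cosine_profile(eps_ce, n_max),
            profile_i=cosine_profile(eps_ci, n_max),
            **kw,
        )

    @property
    def n_max(self) -> int:
        return len(self.profile_e) - 1

    def g(self, post: str, pre: str) -> float:
        return {("E", "E"): self.g_ee, ("E", "I"): self.g_ei,
                ("I", "E"): self.g_ie, ("I", "I"): self.g_ii}[(post, pre)]

    def profile(self, pre: str) -> np.ndarray:
        return self.profile_e if pre == "E" else self.profile_i

    def i_ext_modes(self, pop: str) -> np.ndarray:
        """External-drive Fourier modes: [I_A, rho I_A, 0, ...]."""
        i_a = self.i_ext_e if pop == "E" else self.i_ext_i
        modes = np.zeros(self.n_max + 1)
        modes[0] = i_a
        if self.n_max >= 1:
            modes[1] = self.rho * i_a
        return modes


def fourier_interactions(spec: RingSpec) -> dict[tuple[str, str], np.ndarray]:
    """J_AB(n) = G_AB * C_B(n) for n = 0..n_max (magnitudes)."""
    return {
        (post, pre): spec.g(post, pre) * spec.profile(pre)
        for post in ("E", "I")
        for pre in ("E", "I")
    }


@dataclass
class BalancedSolution:
    nu_e: np.ndarray  # Fourier modes of the excitatory rate profile
    nu_i: np.ndarray
    theta_grid: np.ndarray = field(repr=False)
    rates_e: np.ndarray = field(repr=False)  # reconstructed profile on the grid
    rates_i: np.ndarray = field(repr=False)

    def nu(self, pop: str) -> np.ndarray:
        return self.nu_e if pop == "E" else self.nu_i


def _check_feasibility(spec: RingSpec) -> None:
    j = fourier_interactions(spec)
    lhs = spec.i_ext_e / spec.i_ext_i
    mid = j[("E", "I")][0] / j[("I", "I")][0]
    rhs = j[("E", "E")][0] / j[("I", "E")][0]
    if not lhs > mid:
        raise BalancedStateError(
            f"no balanced state: I_E/I_I = {lhs:.4f} must exceed "
            f"J_EI(0)/J_II(0) = {mid:.4f}"
        )
    if not mid > rhs:
        raise BalancedStateError(
            f"no balanced state: J_EI(0)/J_II(0) = {mid:.4f} must exceed "
            f"J_EE(0)/J_IE(0) = {rhs:.4f}"
        )


def balanced_rates(spec: RingSpec, n_grid: int = 256) -> BalancedSolution:
    """Mode-wise solution of the balance conditions.

    For each mode n solves
        [ J_EE(n)  -J_EI(n) ] [nu_E(n)]   [I_E(n)]
        [ J_IE(n)  -J_II(n) ] [nu_I(n)] = -[I_I(n)] .
    Raises :class:`BalancedStateError` when the mode-0 feasibility fails or
    a driven mode has a singular interaction matrix (the salt-and-pepper
    divergence: modulated drive with an unmodulated recurrent profile).
    """
    _check_feasibility(spec)
    j = fourier_interactions(spec)
    i_e = spec.i_ext_modes("E")
    i_i = spec.i_ext_modes("I")
    nu_e = np.zeros(spec.n_max + 1)
    nu_i = np.zeros(spec.n_max + 1)
    for n in range(spec.n_max + 1):
        a = np.array(
            [
                [j[("E", "E")][n], -j[("E", "I")][n]],
                [j[("I", "E")][n], -j[("I", "I")][n]],
            ]
        )
        rhs = -np.array([i_e[n], i_i[n]])
        det = np.linalg.det(a)
        if abs(det) < 1e-14:
            if np.any(np.abs(rhs) > 0):
                raise BalancedStateError(
                    f"singular interaction matrix at driven mode n={n}: the "
                    "balanced selectivity diverges for an unmodulated "
                    "recurrent profile (finite-K fluctuations take over)"
                )
            continue
        nu_e[n], nu_i[n] = np.linalg.solve(a, rhs)
    if nu_e[0] <= 0 or nu_i[0] <= 0:
        raise BalancedStateError("balance equations give nonpositive mean rates")
    theta = np.arange(n_grid) / n_grid
    rates_e = np.full(n_grid, nu_e[0])
    rates_i = np.full(n_grid, nu_i[0])
    for n in range(1, spec.n_max + 1):
        rates_e += 2.0 * nu_e[n] * np.cos(2 * np.pi * n * theta)
        rates_i += 2.0 * nu_i[n] * np.cos(2 * np.pi * n * theta)
    return BalancedSolution(
        nu_e=nu_e, nu_i=nu_i, theta_grid=theta, rates_e=rates_e, rates_i=rates_i
    )


def selectivity_prediction(spec: RingSpec) -> dict[str, float]:
    """Predicted activity selectivity nu_A(1)/nu_A(0) = rho J_B(0)/J_B(1).

    For the cosine profile with modulation eps this is 2 rho / eps.  Raises
    :class:`BalancedStateError` when a presynaptic profile is unmodulated
    (J_B(1) = 0): the leading-order prediction diverges and selectivity is
    set by finite-K connectivity fluctuations instead.
    """
    out = {}
    for pop, pre in (("E", "E"), ("I", "I")):
        prof = spec.profile(pre)
        if len(prof) < 2 or prof[1] == 0.0:
            raise BalancedStateError(
                f"profile of presynaptic population {pre} is unmodulated; "
                "the balanced-state selectivity prediction diverges"
            )
        out[pop] = spec.rho * prof[0] / prof[1]
    return out


@dataclass
class StabilityReport:
    trace_ok: np.ndarray  # per-mode J_EE(n) - J_II(n) < 0
    det_ok: np.ndarray  # per-mode J_IE J_EI - J_EE J_II > 0
    feasible: bool
    eps_ci_min: float | None = None  # mode-1 boundary given the spec's eps_cE

    @property
    def stable(self) -> bool:
        return bool(self.feasible and self.trace_ok.all() and self.det_ok.all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mode": np.arange(self.trace_ok.size), "trace_ok": self.trace_ok,
             "det_ok": self.det_ok}
        ).set_index("mode")


def _mode_flags(spec: RingSpec) -> tuple[np.ndarray, np.ndarray]:
    j = fourier_interactions(spec)
    trace_ok = j[("E", "E")] - j[("I", "I")] < 0
    det_ok = j[("I", "E")] * j[("E", "I")] - j[("E", "E")] * j[("I", "I")] > 0
    # an undriven, unconnected mode (all J(n) = 0) is trivially stable
    zero = np.all(
        [np.abs(j[key]) < 1e-15 for key in j], axis=0
    )
    return trace_ok | zero, det_ok | zero


def stability_report(
    spec: RingSpec,
    eps_ce: float | None = None,
    tol: float = 1e-12,
) -> StabilityReport:
    """Per-mode stability flags, feasibility, and the eps_cI boundary.

    When ``eps_ce`` is given (or recoverable from the profile), the minimal
    inhibitory reconnection modulation keeping mode 1 stable is located by
    bisection on the mode-1 stability verdict: below the boundary the
    excitatory modulated input cannot be compensated by the recurrent
    inhibition and the balanced state loses stability at mode 1.
    """
    trace_ok, det_ok = _mode_flags(spec)
    try:
        _check_feasibility(spec)
        feasible = True
    except BalancedStateError:
        feasible = False

    eps_ci_min = None
    if eps_ce is None and spec.n_max >= 1 and spec.profile_e[1] > 0:
        eps_ce = 2.0 * spec.profile_e[1]
    if eps_ce is not None and eps_ce > 0:

        def mode1_stable(eps_ci: float) -> bool:
            j_ee1 = spec.g_ee * eps_ce / 2.0
            j_ii1 = spec.g_ii * eps_ci / 2.0
            j_ie1 = spec.g_ie * eps_ce / 2.0
            j_ei1 = spec.g_ei * eps_ci / 2.0
            return (j_ee1 - j_ii1 < 0) and (j_ie1 * j_ei1 - j_ee1 * j_ii1 > 0)

        lo, hi = 0.0, 1.0
        if mode1_stable(lo):
            eps_ci_min = 0.0
        elif not mode1_stable(hi):
            eps_ci_min = np.inf  # unattainable within the admissible range
        else:
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if mode1_stable(mid):
                    hi = mid
                else:
                    lo = mid
            eps_ci_min = 0.5 * (lo + hi)
    return StabilityReport(
        trace_ok=trace_ok, det_ok=det_ok, feasible=feasible, eps_ci_min=eps_ci_min
    )


@dataclass
class STDPTheory:
    dj0: float  # drift of the mean interaction mode, per unit time
    dj1: float  # drift of the modulated mode
    d_selectivity: float | None  # first-order change of rho J(0)/J(1)


def stdp_theory(
    nu_post: float,
    nu_pre: float,
    xi_post: float,
    xi_pre: float,
    alpha: float,
    j0: float | None = None,
    j1: float | None = None,
    rho: float = 0.06,
) -> STDPTheory:
    """Predicted drift of the interaction Fourier modes under slow STDP.

    With uncorrelated trains the mean pair drift is alpha nu_post nu_pre
    times ``(1 + 2 xi_post xi_pre cos(2 pi dPO))``; its mode-0 part grows
    the mean coupling, its mode-1 part (proportional to the *square* of the
    selectivity for a homogeneous population) builds functional
    connectivity.  Given the current profile modes (j0, j1), the first-order
    change of the activity selectivity rho j0/j1 is also returned: the mean
    growth raises selectivity, the modulation growth lowers it.

    ``xi`` beyond 0.5 (a measured selectivity index rather than a cosine
    modulation depth) is accepted; the quadratic dependence still holds as a
    first-order statement.
    """
    for name, xi in (("xi_post", xi_post), ("xi_pre", xi_pre)):
        if not 0.0 <= xi <= 1.0:
            raise ValueError(f"{name}={xi} outside [0, 1]")
    dj0 = alpha * nu_post * nu_pre
    dj1 = alpha * nu_post * nu_pre * xi_post * xi_pre
    d_sel = None
    if j0 is not None and j1 is not None and j1 != 0:
        d_sel = rho * (dj0 * j1 - j0 * dj1) / j1**2
    return STDPTheory(dj0=dj0, dj1=dj1, d_selectivity=d_sel)
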