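"""Experiment configuration, defaults, and figure-style presets.

Every published default parameter is a named field; a config file (YAML)
only lists overrides, unknown keys are rejected, and derived quantities
(g_AB = G_AB/sqrt(K), the feed-forward sqrt(K/K_ref) factor) follow K
automatically.  A digest of the fully-resolved config is embedded in every
output so a run can be reproduced from its artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .params import (
    DEFAULT_ANGLES_DEG,
    FeedforwardParams,
    NeuronParams,
    PlasticitySchedule,
    RecurrentParams,
    SimProtocol,
    STDPParams,
)
from .connectivity import ConnectivityParams, ReconnectionParams

__all__ = ["ExperimentConfig", "load_config", "save_config", "preset", "PRESETS"]


@dataclass(frozen=True)
class ExperimentConfig:
    # membrane
    tau: float = 20.0
    r_m: float = 38.3
    v_t: float = 30.0
    v_reset: float = 0.0
    # recurrent couplings (signed) and synapses
    g_ee: float = 32.0
    g_ei: float = -96.0
    g_ie: float = 96.0
    g_ii: float = -128.0
    tau_syn_e: float = 25.0
    tau_syn_i: float = 4.0
    k: float = 500.0
    i_back_e: float = 0.12
    i_back_i: float = 0.12
    # feed-forward
    g_al: float = 1.65
    k_al: int = 250
    fr_l: float = 15.0
    rho_e: float = 0.06
    rho_i: float = 0.06
    ff_ref_k: float | None = 500.0
    # geometry / layout
    n_e: int = 8100
    n_i: int = 2025
    m: float = 1.0
    sigma: float = 0.2
    layout: str = "random"
    # protocol
    dt: float = 0.05
    t_total: float = 20_000.0
    t_transient: float = 100.0
    angles_deg: tuple = DEFAULT_ANGLES_DEG
    seed: int = 0
    max_rate_hz: float = 250.0
    # plasticity
    a_plus: float = 0.0128
    a_minus: float = -0.0045
    tau_plus: float = 30.0
    tau_minus: float = 40.0
    t_plastic: float = 13_333.0
    t_measure: float = 6_667.0
    theta_train_deg: float = 0.0
    # reconnection
    eps_ce: float = 0.0
    eps_ci: float = 0.0

    # ---- derived views ----------------------------------------------------
    def neuron_params(self) -> NeuronParams:
        return NeuronParams(tau=self.tau, r_m=self.r_m, v_t=self.v_t, v_reset=self.v_reset)

    def ff_params(self) -> FeedforwardParams:
        return FeedforwardParams(
            g_al=self.g_al, k_al=self.k_al, fr_l=self.fr_l,
            rho_e=self.rho_e, rho_i=self.rho_i, ff_ref_k=self.ff_ref_k,
        )

    def rec_params(self) -> RecurrentParams:
        return RecurrentParams(
            g_ee=self.g_ee, g_ei=self.g_ei, g_ie=self.g_ie, g_ii=self.g_ii,
            tau_syn_e=self.tau_syn_e, tau_syn_i=self.tau_syn_i, k=self.k,
            i_back_e=self.i_back_e, i_back_i=self.i_back_i,
        )

    def conn_params(self) -> ConnectivityParams:
        return ConnectivityParams(k=self.k, sigma=self.sigma)

    def stdp_params(self) -> STDPParams:
        return STDPParams(
            a_plus=self.a_plus, a_minus=self.a_minus,
            tau_plus=self.tau_plus, tau_minus=self.tau_minus,
        )

    def schedule(self) -> PlasticitySchedule:
        return PlasticitySchedule(
            t_plastic=self.t_plastic, t_measure=self.t_measure,
            theta_train_deg=self.theta_train_deg,
        )

    def protocol(self, t_total: float | None = None) -> SimProtocol:
        return SimProtocol(
            dt=self.dt,
            t_total=self.t_total if t_total is None else t_total,
            t_transient=self.t_transient,
            angles_deg=tuple(self.angles_deg),
            seed=self.seed,
            max_rate_hz=self.max_rate_hz,
        )

    def reconnection_params(self) -> ReconnectionParams:
        return ReconnectionParams(eps_ce=self.eps_ce, eps_ci=self.eps_ci)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_overrides(self, **kw) -> "ExperimentConfig":
        return replace(self, **_validated(kw))


_FIELDS = {f.name: f for f in fields(ExperimentConfig)}


def _validated(overrides: dict) -> dict:
    out = {}
    for key, value in overrides.items():
        if key not in _FIELDS:
            raise KeyError(f"unknown configuration key {key!r}")
        default = getattr(ExperimentConfig, key)
        if key == "angles_deg":
            try:
                value = tuple(float(v) for v in value)
            except (TypeError, ValueError):
                raise TypeError("angles_deg must be a sequence of angles in degrees")
        elif key == "layout":
            if value not in ("map", "random"):
                raise TypeError(f"layout must be 'map' or 'random', got {value!r}")
        elif key == "ff_ref_k":
            if value is not None and not isinstance(value, (int, float)):
                raise TypeError("ff_ref_k must be a number or null")
        elif isinstance(default, bool):
            if not isinstance(value, bool):
                raise TypeError(f"{key} must be a boolean, got {value!r}")
        elif isinstance(default, int) and not isinstance(default, bool):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise TypeError(f"{key} must be a number, got {value!r}")
            if float(value) != int(value):
                raise TypeError(f"{key} must be an integer, got {value!r}")
            value = int(value)
        elif isinstance(default, float):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise TypeError(f"{key} must be a number, got {value!r}")
            value = float(value)
        out[key] = value
    return out


def load_config(path) -> ExperimentConfig:
    """Read a YAML config of overrides; an empty file gives all defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise TypeError(f"config root must be a mapping, got {type(raw).__name__}")
    return ExperimentConfig(**_validated(raw))


def save_config(cfg: ExperimentConfig, path) -> None:
    payload = asdict(cfg)
    payload["angles_deg"] = list(payload["angles_deg"])
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


# ---- presets ---------------------------------------------------------------

# Desk scale: smaller grids and shorter runs for single-CPU turnaround.  The
# feed-forward drive follows K automatically through ff_ref_k, so K_AL stays
# at its default and only the network and durations shrink.
_DESK = dict(n_e=1600, n_i=400, k=100.0, t_total=5_000.0,
             t_plastic=3_333.0, t_measure=1_667.0)


def _desk(cfg: ExperimentConfig) -> ExperimentConfig:
    return cfg.with_overrides(**_DESK)


def preset(name: str, scale: str = "desk") -> dict:
    """Named experiment presets at ``full`` (published) or ``desk`` scale.

    Returns ``{"config": ExperimentConfig, "plan": [variant dicts], "scaled": bool}``;
    desk scale shrinks the network and run lengths for single-CPU turnaround
    and is meant for directional claims only.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    if scale not in ("full", "desk"):
        raise ValueError("scale must be 'full' or 'desk'")
    base, plan = PRESETS[name]
    cfg = ExperimentConfig(**_validated(base))
    if scale == "desk":
        cfg = _desk(cfg)
        if name == "fig3":
            plan = [{**v, "k": {250.0: 100.0, 1000.0: 400.0}[v["k"]]} for v in plan]
    return {"config": cfg, "plan": [dict(v) for v in plan], "scaled": scale == "desk"}


PRESETS = {
    # balanced-scaling demonstration: input components vs K on one probed neuron
    "fig3": (
        dict(n_e=16129, n_i=4096, layout="random"),
        [{"k": 250.0, "probe": 0}, {"k": 1000.0, "probe": 0}],
    ),
    # selectivity of map vs salt-and-pepper layouts
    "fig4": (dict(), [{"layout": "map"}, {"layout": "random"}]),
    # STDP before/after OSI distributions for both layouts
    "fig5": (dict(), [{"layout": "map", "stdp": True}, {"layout": "random", "stdp": True}]),
    # functional-connectivity fit of final efficacies vs PO difference
    "fig6": (dict(), [{"layout": "random", "stdp": True, "fit_dw": True},
                      {"layout": "map", "stdp": True, "fit_dw": True}]),
    # reconnection grids in the stable regime
    "fig8": (
        dict(layout="random"),
        [{"grid": "eps_ce", "values": [0.11, 0.22, 0.44, 0.66, 0.88], "eps_ci": 0.22},
         {"grid": "eps_ci", "values": [0.11, 0.22, 0.44, 0.66, 0.88], "eps_ce": 0.44}],
    ),
    # reconnection into the unstable regime
    "fig9": (
        dict(layout="random"),
        [{"grid": "eps_ci", "values": [0.03, 0.05, 0.08], "eps_ce": 0.44}],
    ),
    # analytic ring model only
    "reduced": (dict(), [{"eps_ce": 0.44, "eps_ci": 0.22}]),
}
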