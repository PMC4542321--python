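"""Serialization: layouts and rasters as delimited text, graphs as npz.

Graph snapshots are portable npz containers holding three aligned arrays per
population pair (post index, pre index, efficacy) plus a JSON header with
seeds and sampling parameters; edge lists can also be exported as TSV.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import sparse

from .connectivity import ConnectivityGraph, ConnectivityParams, ReconnectionParams
from .geometry import LayerGeometry, OrientationLayout, build_geometry
from .simulate import SpikeData

__all__ = [
    "save_layout",
    "load_layout",
    "save_graph",
    "load_graph",
    "export_edge_list",
    "save_spikes",
    "load_spikes",
    "save_tuning",
]


def save_layout(path, geom: LayerGeometry, layout: OrientationLayout, digest: str = "") -> None:
    frames = []
    for pop in ("E", "I"):
        pos = geom.positions(pop)
        frames.append(
            pd.DataFrame(
                {
                    "neuron": np.arange(pos.shape[0]),
                    "population": pop,
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "theta_deg": np.rad2deg(layout.theta(pop)),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# balv1 layout mode={layout.mode} M={geom.m} digest={digest}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def load_layout(path) -> tuple[LayerGeometry, OrientationLayout]:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, sep="\t")
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv)
    mode = meta.get("mode", "random")
    m = float(meta.get("M", 1.0))
    n_e = int((df["population"] == "E").sum())
    n_i = int((df["population"] == "I").sum())
    geom = build_geometry(n_e, n_i, m)
    theta = {
        pop: np.deg2rad(
            df.loc[df["population"] == pop].sort_values("neuron")["theta_deg"].to_numpy()
        )
        for pop in ("E", "I")
    }
    return geom, OrientationLayout(mode=mode, theta_e=theta["E"], theta_i=theta["I"])


def save_graph(path, graph: ConnectivityGraph, extra_meta: dict | None = None) -> None:
    arrays = {}
    for (post, pre), block in graph.blocks.items():
        coo = block.tocoo()
        arrays[f"{post}{pre}_post"] = coo.row.astype(np.int64)
        arrays[f"{post}{pre}_pre"] = coo.col.astype(np.int64)
        arrays[f"{post}{pre}_w"] = coo.data.astype(np.float64)
    meta = {
        "n_e": graph.geom.n_e,
        "n_i": graph.geom.n_i,
        "m": graph.geom.m,
        "k": graph.params.k,
        "sigma": graph.params.sigma,
        "k_max": graph.params.k_max,
        "seed": graph.seed,
        "eps_ce": graph.reconnection.eps_ce if graph.reconnection else None,
        "eps_ci": graph.reconnection.eps_ci if graph.reconnection else None,
        "clamp_count": graph.clamp_count,
    }
    if extra_meta:
        meta.update(extra_meta)
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_graph(path) -> ConnectivityGraph:
    data = np.load(path)
    meta = json.loads(bytes(data["meta_json"]).decode())
    geom = build_geometry(meta["n_e"], meta["n_i"], meta["m"])
    shapes = {"E": meta["n_e"], "I": meta["n_i"]}
    blocks = {}
    for post in ("E", "I"):
        for pre in ("E", "I"):
            key = f"{post}{pre}"
            blocks[(post, pre)] = sparse.csr_matrix(
                (data[f"{key}_w"], (data[f"{key}_post"], data[f"{key}_pre"])),
                shape=(shapes[post], shapes[pre]),
            )
    rec = None
    if meta.get("eps_ce") is not None:
        rec = ReconnectionParams(eps_ce=meta["eps_ce"], eps_ci=meta["eps_ci"])
    return ConnectivityGraph(
        geom=geom,
        params=ConnectivityParams(k=meta["k"], sigma=meta["sigma"], k_max=meta["k_max"]),
        blocks=blocks,
        seed=meta.get("seed"),
        reconnection=rec,
        clamp_count=meta.get("clamp_count", 0),
    )


def export_edge_list(path, graph: ConnectivityGraph) -> None:
    rows = []
    for (post, pre), block in graph.blocks.items():
        coo = block.tocoo()
        rows.append(
            pd.DataFrame(
                {"post_pop": post, "pre_pop": pre, "post": coo.row, "pre": coo.col,
                 "w": coo.data}
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def save_spikes(path, spikes: SpikeData, digest: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# balv1 raster n_e={spikes.n_e} n_i={spikes.n_i} "
            f"t_total={spikes.t_total} t_transient={spikes.t_transient} digest={digest}\n"
        )
        spikes.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")


def load_spikes(path) -> SpikeData:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, sep="\t")
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv)
    out = SpikeData(
        n_e=int(meta["n_e"]),
        n_i=int(meta["n_i"]),
        t_total=float(meta["t_total"]),
        t_transient=float(meta["t_transient"]),
    )
    for angle, grp in df.groupby("angle_deg"):
        idx = np.where(grp["population"] == "E", grp["neuron"], grp["neuron"] + out.n_e)
        out.spikes[float(angle)] = (
            idx.astype(np.int64),
            grp["time_ms"].to_numpy(dtype=float),
        )
    return out


def save_tuning(path, tuning, digest: str = "") -> None:
    n = tuning.osi.size
    pop = np.where(np.arange(n) < tuning.n_e, "E", "I")
    local = np.where(np.arange(n) < tuning.n_e, np.arange(n), np.arange(n) - tuning.n_e)
    df = pd.DataFrame({"population": pop, "neuron": local, "osi": tuning.osi,
                       "po_deg": tuning.po_deg})
    for a, angle in enumerate(tuning.angles_deg):
        df[f"rate_hz_{angle:g}"] = tuning.rates[:, a]
    with open(path, "w") as fh:
        fh.write(f"# balv1 tuning digest={digest}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")
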