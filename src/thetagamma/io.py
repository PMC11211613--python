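"""Persistence of traces, weights and tables.

Simulation traces and weight snapshots go into an HDF5 container with named
channels and run attributes; success tables are written as columnar text
(the layout of the reference tables) with a machine-readable JSON twin;
synapse matrices can also be exported as columnar text
(post_id, pre_id, kind, weight).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .network import ConnectionSet, Network, SimulationResult
from .assessment import SuccessTable

__all__ = [
    "save_result",
    "load_result_arrays",
    "save_weights",
    "load_weights",
    "weights_to_text",
    "save_table",
]


def save_result(path, result: SimulationResult, config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["dt"] = result.dt
        f.attrs["duration"] = result.duration
        f.attrs["mode"] = result.mode
        f.attrs["seed"] = -1 if result.seed is None else result.seed
        f.attrs["config_hash"] = config_hash
        f.create_dataset("theta", data=result.theta, compression="gzip")
        for name, arr in result.z.items():
            f.create_dataset(f"z_{name}", data=arr, compression="gzip")


def load_result_arrays(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        out["attrs"] = dict(f.attrs)
        for k in f:
            out[k] = f[k][...]
    return out


def save_weights(path, conn: ConnectionSet, config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        for kind, m in conn.plastic.items():
            f.create_dataset(kind, data=m, compression="gzip")
        f.attrs["k_wm_l1"] = conn.k_wm_l1
        f.attrs["k_l1_l2"] = conn.k_l1_l2
        f.attrs["k_theta"] = conn.k_theta


def load_weights(path, network: Network, expect_hash: str | None = None) -> Network:
    """Load a weight snapshot into a copy of ``network``.

    Reloading and re-running with the same seed reproduces retrieval
    behavior bit-for-bit.
    """
    net = network.copy()
    with h5py.File(path, "r") as f:
        if expect_hash is not None and f.attrs.get("config_hash", "") != expect_hash:
            raise ValueError("config hash mismatch on weight reload")
        c = net.connections
        c.wp_l1l1 = f["Wp_L1L1"][...]
        c.wf_l1l1 = f["Wf_L1L1"][...]
        c.af_l1l1 = f["Af_L1L1"][...]
        c.wp_l1l2 = f["Wp_L1L2"][...]
        c.k_wm_l1 = float(f.attrs["k_wm_l1"])
        c.k_l1_l2 = float(f.attrs["k_l1_l2"])
        c.k_theta = float(f.attrs["k_theta"])
    return net


def weights_to_text(path, conn: ConnectionSet, threshold: float = 1e-9) -> None:
    """Columnar text export: post_id, pre_id, kind, weight (1-based ids)."""
    lines = ["post_id\tpre_id\tkind\tweight"]
    for kind, m in conn.plastic.items():
        post, pre = np.nonzero(m > threshold)
        for i, j in zip(post, pre):
            lines.append(f"{i + 1}\t{j + 1}\t{kind}\t{m[i, j]:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_table(path_prefix, table: SuccessTable) -> None:
    """Write the columnar text table plus a JSON twin."""
    p = Path(path_prefix)
    p.with_suffix(".txt").write_text(str(table) + "\n")
    doc = {
        "values": table.values.tolist(),
        "mean": table.mean_row.tolist(),
        "n_runs": table.n_runs,
        "cycles_per_run": table.cycles_per_run,
        "meta": table.meta,
    }
    p.with_suffix(".json").write_text(json.dumps(doc, indent=2))
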