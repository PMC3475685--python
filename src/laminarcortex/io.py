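"""Result containers on disk: HDF5 round-trip and CSV export."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectome import ConnectionMap
from .model import SimulationResult
from .params import LAYERS, ModelParams


def save_result(result: SimulationResult, path: str | Path) -> None:
    """Write a :class:`SimulationResult` to an HDF5 container.

    One dataset per (layer, population) trace plus optional line recordings;
    seed, schedule and the full parameter set are stored as attributes.
    """
    with h5py.File(path, "w") as f:
        for li, layer in enumerate(LAYERS):
            grp = f.create_group(f"layer_{li}")
            grp.attrs["label"] = layer
            grp.create_dataset("potential_e", data=result.potentials[:, li, 0])
            grp.create_dataset("potential_i", data=result.potentials[:, li, 1])
            if result.line is not None:
                grp.create_dataset("line_e", data=result.line[:, li, 0])
                grp.create_dataset("line_i", data=result.line[:, li, 1])
        f.attrs["dt_ms"] = result.dt
        f.attrs["warmup_ms"] = result.warmup_ms
        f.attrs["stim_ms"] = result.stim_ms
        f.attrs["seed"] = result.seed
        f.attrs["protocol_kind"] = result.protocol_kind
        f.attrs["params_digest"] = result.params_digest
        f.attrs["params_json"] = json.dumps(result.params.to_dict())


def load_result(path: str | Path) -> SimulationResult:
    """Read a :class:`SimulationResult` written by :func:`save_result`."""
    with h5py.File(path, "r") as f:
        n_steps = f["layer_0/potential_e"].shape[0]
        potentials = np.empty((n_steps, len(LAYERS), 2))
        line = None
        for li in range(len(LAYERS)):
            grp = f[f"layer_{li}"]
            potentials[:, li, 0] = grp["potential_e"][:]
            potentials[:, li, 1] = grp["potential_i"][:]
            if "line_e" in grp:
                if line is None:
                    n = grp["line_e"].shape[1]
                    line = np.empty((n_steps, len(LAYERS), 2, n))
                line[:, li, 0] = grp["line_e"][:]
                line[:, li, 1] = grp["line_i"][:]
        params = ModelParams.from_dict(json.loads(f.attrs["params_json"]))
        return SimulationResult(
            potentials=potentials, dt=float(f.attrs["dt_ms"]),
            warmup_ms=float(f.attrs["warmup_ms"]), stim_ms=float(f.attrs["stim_ms"]),
            seed=int(f.attrs["seed"]), params=params,
            protocol_kind=str(f.attrs["protocol_kind"]),
            params_digest=str(f.attrs["params_digest"]), line=line)


def traces_frame(result: SimulationResult) -> pd.DataFrame:
    """Central-element traces as a tidy DataFrame (one column per trace)."""
    data = {"time_ms": result.times}
    for li, layer in enumerate(LAYERS):
        safe = layer.replace("/", "-")
        data[f"V_{safe}_E"] = result.potentials[:, li, 0]
        data[f"V_{safe}_I"] = result.potentials[:, li, 1]
    data["lfp"] = result.lfp()
    return pd.DataFrame(data)


def export_traces_csv(result: SimulationResult, path: str | Path) -> None:
    traces_frame(result).to_csv(path, index=False)


def save_connection_map(cmap: ConnectionMap, path: str | Path) -> None:
    cmap.save(path)


def load_connection_map(path: str | Path) -> ConnectionMap:
    return ConnectionMap.load(path)
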