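"""YAML run configuration: load/save a full run specification.

A config file holds the model parameters (any subset; the rest take their
calibrated defaults), the stimulation protocol, the schedule, the seed and
optionally the path of a connection-map file::

    params:
      grid_n: 10
      gain_e: 4.8e-5
    protocol:
      kind: constant_visual
    schedule:
      warmup_ms: 60000
      stim_ms: 20000
    seed: 7
    connection_map: maps/custom.tsv   # optional; default map if omitted
    record_line: false
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .connectome import ConnectionMap
from .exceptions import ConfigError
from .model import RunConfig
from .params import ModelParams
from .stimulus import StimulusProtocol


def config_from_dict(doc: dict, base_dir: str | Path = ".") -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("run configuration must be a mapping")
    known = {"params", "protocol", "schedule", "seed", "connection_map",
             "record_line"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    params = ModelParams.from_dict(doc.get("params", {}) | {})
    proto_doc = doc.get("protocol", {})
    protocol = StimulusProtocol(**{k: tuple(map(tuple, v)) if k == "source_elements"
                                   else v for k, v in proto_doc.items()})
    schedule = doc.get("schedule", {})
    cmap = None
    if doc.get("connection_map"):
        cmap = ConnectionMap.load(Path(base_dir) / doc["connection_map"])
    return RunConfig(params=params, connection_map=cmap, protocol=protocol,
                     warmup_ms=float(schedule.get("warmup_ms", 60000.0)),
                     stim_ms=float(schedule.get("stim_ms", 20000.0)),
                     seed=int(doc.get("seed", 0)),
                     record_line=bool(doc.get("record_line", False)))


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    doc = yaml.safe_load(path.read_text()) or {}
    return config_from_dict(doc, base_dir=path.parent)


def config_to_dict(config: RunConfig) -> dict:
    doc = {
        "params": config.params.to_dict(),
        "protocol": dataclasses.asdict(config.protocol),
        "schedule": {"warmup_ms": config.warmup_ms, "stim_ms": config.stim_ms},
        "seed": config.seed,
        "record_line": config.record_line,
    }
    doc["protocol"]["source_elements"] = [list(e) for e
                                          in config.protocol.source_elements]
    return doc


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
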