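"""Laminar synaptic connection map.

Each entry gives the number of synapses a target population (layer x E/I)
receives from one source: either a cortical population (layer x E/I, category
``intracortical``) or an external afferent category (``thalamic`` projections
from the LGN, or ``cortico-cortical`` synapses from other cortical areas that
contribute background noise).

The shipped default map is a structural stand-in: it encodes the qualitative
laminar circuit of visual cortex (thalamic input to layers IV, V and VI, the
IV -> II/III -> V -> VI -> IV relay, and within-layer E/I loops) with relative
synapse counts chosen during calibration.  It is not a literal anatomical
synapse census; users can edit the tabular file form freely.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

from .exceptions import ConfigError
from .params import LAYERS, layer_index

EXTERNAL = "external"
CATEGORIES = ("intracortical", "cortico-cortical", "thalamic")
#: Layers receiving direct thalamic (LGN) afferents.
THALAMIC_TARGET_LAYERS = ("IV", "V", "VI")


@dataclass(frozen=True)
class Connection:
    """One entry of the connection map.

    ``source_layer`` is a layer label for intracortical entries, or the
    literal string ``"external"`` with ``source_pop`` naming the afferent
    category (``"thalamic"`` / ``"cortico-cortical"``).
    """

    source_layer: str
    source_pop: str
    target_layer: str
    target_pop: str
    count: float
    category: str

    @property
    def is_external(self) -> bool:
        return self.source_layer == EXTERNAL

    def validate(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigError(f"unknown connection category {self.category!r}")
        if self.count < 0:
            raise ConfigError(f"synapse count must be non-negative, got {self.count}")
        layer_index(self.target_layer)
        if self.target_pop not in ("E", "I"):
            raise ConfigError(f"target population must be E or I, got {self.target_pop!r}")
        if self.is_external:
            if self.source_pop not in ("thalamic", "cortico-cortical"):
                raise ConfigError(
                    f"external source must be thalamic or cortico-cortical, got {self.source_pop!r}")
            if self.source_pop != self.category:
                raise ConfigError("external entry category must match its source")
            if self.source_pop == "thalamic" and self.target_layer not in THALAMIC_TARGET_LAYERS:
                raise ConfigError(
                    f"thalamic afferents target layers {THALAMIC_TARGET_LAYERS} only, "
                    f"got layer {self.target_layer}")
        else:
            layer_index(self.source_layer)
            if self.source_pop not in ("E", "I"):
                raise ConfigError(f"source population must be E or I, got {self.source_pop!r}")
            if self.category != "intracortical":
                raise ConfigError("cortical sources must be labelled intracortical")
            # Inhibitory axons do not project between areas, and in this map
            # not between laminae either: inhibition is local.
            if self.source_pop == "I" and self.source_layer != self.target_layer:
                raise ConfigError(
                    f"inhibitory sources project only within their layer "
                    f"({self.source_layer} -> {self.target_layer} rejected)")


_COLUMNS = ("source_layer", "source_pop", "target_layer", "target_pop",
            "synapse_count", "category")


class ConnectionMap:
    """An ordered collection of :class:`Connection` entries."""

    def __init__(self, entries: list[Connection]):
        for e in entries:
            e.validate()
        self.entries = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, ConnectionMap) and self.entries == other.entries

    # -- queries -----------------------------------------------------------
    def intracortical(self) -> list[Connection]:
        return [e for e in self.entries if not e.is_external]

    def external(self, category: str) -> list[Connection]:
        return [e for e in self.entries if e.is_external and e.category == category]

    def scale_source_layer(self, layer: str, factor: float) -> "ConnectionMap":
        """Scale every entry whose presynaptic neurons sit in ``layer``.

        Used for the layer-IV reduction scenario: a factor of 0.5 halves all
        synapses formed with presynaptic neurons of the given layer (both
        excitatory and inhibitory sources).
        """
        layer_index(layer)
        out = []
        for e in self.entries:
            if not e.is_external and e.source_layer == layer:
                e = replace(e, count=e.count * factor)
            out.append(e)
        return ConnectionMap(out)

    # -- serialization (tab-separated text, lossless round-trip) -----------
    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("\t".join(_COLUMNS) + "\n")
        for e in self.entries:
            buf.write(f"{e.source_layer}\t{e.source_pop}\t{e.target_layer}\t"
                      f"{e.target_pop}\t{e.count!r}\t{e.category}\n")
        return buf.getvalue()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())

    @classmethod
    def from_tsv(cls, text: str) -> "ConnectionMap":
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        header = tuple(lines[0].split("\t"))
        if header != _COLUMNS:
            raise ConfigError(f"connection map header must be {_COLUMNS}, got {header}")
        entries = []
        for ln in lines[1:]:
            parts = ln.split("\t")
            if len(parts) != len(_COLUMNS):
                raise ConfigError(f"malformed connection map row: {ln!r}")
            sl, sp, tl, tp, cnt, cat = parts
            entries.append(Connection(sl, sp, tl, tp, float(cnt), cat))
        return cls(entries)

    @classmethod
    def load(cls, path: str | Path) -> "ConnectionMap":
        return cls.from_tsv(Path(path).read_text())


def _within(layer: str, e_e: float, e_i: float, i_e: float, i_i: float) -> list[Connection]:
    return [
        Connection(layer, "E", layer, "E", e_e, "intracortical"),
        Connection(layer, "E", layer, "I", e_i, "intracortical"),
        Connection(layer, "I", layer, "E", i_e, "intracortical"),
        Connection(layer, "I", layer, "I", i_i, "intracortical"),
    ]


def default_connection_map() -> ConnectionMap:
    """The default laminar circuit (structural stand-in, see module docs)."""
    entries: list[Connection] = []
    # Within-layer excitatory/inhibitory loops.  Layer IV carries stronger
    # local feedforward inhibition than the other laminae, as expected for
    # the thalamorecipient layer.
    for layer in LAYERS:
        if layer == "IV":
            entries += _within(layer, e_e=150.0, e_i=450.0, i_e=450.0, i_i=100.0)
        else:
            entries += _within(layer, e_e=150.0, e_i=350.0, i_e=300.0, i_i=100.0)
    # Interlaminar excitatory relay (IV -> II/III -> V -> VI -> IV).
    relay = [
        ("IV", "II/III", 200.0, 100.0),
        ("II/III", "V", 200.0, 100.0),
        ("V", "VI", 150.0, 75.0),
        ("VI", "IV", 150.0, 75.0),
    ]
    for src, tgt, c_e, c_i in relay:
        entries.append(Connection(src, "E", tgt, "E", c_e, "intracortical"))
        entries.append(Connection(src, "E", tgt, "I", c_i, "intracortical"))
    # Thalamic (LGN) afferents to the input layers; layer V receives only a
    # weak collateral, keeping IV and VI the dominant input laminae.
    thalamic = [("IV", 400.0, 200.0), ("V", 60.0, 30.0), ("VI", 350.0, 175.0)]
    for tgt, c_e, c_i in thalamic:
        entries.append(Connection(EXTERNAL, "thalamic", tgt, "E", c_e, "thalamic"))
        entries.append(Connection(EXTERNAL, "thalamic", tgt, "I", c_i, "thalamic"))
    # Cortico-cortical synapses from other areas: diffuse background drive.
    for layer in LAYERS:
        entries.append(Connection(EXTERNAL, "cortico-cortical", layer, "E", 250.0,
                                  "cortico-cortical"))
        entries.append(Connection(EXTERNAL, "cortico-cortical", layer, "I", 83.0,
                                  "cortico-cortical"))
    return ConnectionMap(entries)
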