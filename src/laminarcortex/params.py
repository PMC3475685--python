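"""Model parameters for the laminar continuum cortex simulator.

Every electrophysiological, propagation, synaptic and numerical constant of
the model lives in :class:`ModelParams`.  The excitatory and inhibitory
synaptic gains are the model's free parameters; the shipped defaults are the
calibrated pair that keeps the spontaneous LFP spectrum 1/f-like, lets
visual stimulation raise gamma-band power, and keeps every population within
10 mV of rest over a full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .exceptions import ParameterError

#: Cortical laminae, superficial to deep.  Layers II and III are merged, as
#: is conventional for visual cortex.
LAYERS: tuple[str, ...] = ("I", "II/III", "IV", "V", "VI")

#: Population index within each element: excitatory first.
POPULATIONS: tuple[str, ...] = ("E", "I")

N_LAYERS = len(LAYERS)


def layer_index(name: str) -> int:
    """Map a layer label (``"IV"``) to its index in :data:`LAYERS`."""
    try:
        return LAYERS.index(name)
    except ValueError:
        raise ParameterError(f"unknown cortical layer {name!r}; expected one of {LAYERS}")


@dataclass(frozen=True)
class ModelParams:
    """All constants of the laminar continuum model.

    Units follow the field's conventions: potentials in mV, times in ms,
    rates in spikes/s, conduction speeds in m/s, distances in mm, synaptic
    gains in V/spike (peak postsynaptic potential evoked per afferent spike).
    """

    # -- electrophysiology -------------------------------------------------
    resting_potential_e: float = -64.0   # mV
    resting_potential_i: float = -64.0   # mV
    sigmoid_qmax: float = 100.0          # spikes/s, population firing ceiling
    sigmoid_theta: float = -54.0         # mV, half-activation threshold
    sigmoid_slope: float = 3.0           # mV, sigmoid steepness
    membrane_time_constant_e: float = 15.0  # ms
    membrane_time_constant_i: float = 15.0  # ms

    # -- synaptic transmission (free gains + PSP kernel time constants) ----
    gain_e: float = 4.8e-5               # V/spike, calibrated default
    gain_i: float = 1.08e-4              # V/spike, calibrated default
    psp_rise_e: float = 1.0              # ms
    psp_decay_e: float = 10.0            # ms
    psp_rise_i: float = 2.0              # ms
    psp_decay_i: float = 20.0            # ms

    # -- spike propagation -------------------------------------------------
    speed_horizontal: float = 0.24       # m/s, lateral conduction speed
    speed_vertical: float | None = None  # m/s; defaults to 1.2 x horizontal
    range_e: float = 2.0                 # mm, lateral spread of E axons
    range_i: float = 0.5                 # mm, lateral spread of I axons

    # -- geometry ----------------------------------------------------------
    grid_n: int = 20                     # elements per side of each layer
    element_spacing: float = 0.5         # mm between adjacent elements
    layer_spacing: float = 0.3           # mm between adjacent laminae

    # -- numerics ----------------------------------------------------------
    dt: float = 1.0                      # ms, fixed integration step

    # -- neuron counts per element, used as LFP aggregation weights --------
    neurons_e_per_layer: tuple[float, ...] = (1600.0, 24000.0, 24000.0, 16000.0, 16000.0)
    neurons_i_per_layer: tuple[float, ...] = (400.0, 6000.0, 6000.0, 4000.0, 4000.0)

    def __post_init__(self):
        pos = {
            "sigmoid_qmax": self.sigmoid_qmax,
            "sigmoid_slope": self.sigmoid_slope,
            "membrane_time_constant_e": self.membrane_time_constant_e,
            "membrane_time_constant_i": self.membrane_time_constant_i,
            "psp_rise_e": self.psp_rise_e,
            "psp_decay_e": self.psp_decay_e,
            "psp_rise_i": self.psp_rise_i,
            "psp_decay_i": self.psp_decay_i,
            "speed_horizontal": self.speed_horizontal,
            "range_e": self.range_e,
            "range_i": self.range_i,
            "element_spacing": self.element_spacing,
            "layer_spacing": self.layer_spacing,
        }
        for name, value in pos.items():
            if not value > 0:
                raise ParameterError(f"{name} must be strictly positive, got {value}")
        if self.speed_vertical is not None and not self.speed_vertical > 0:
            raise ParameterError("speed_vertical must be strictly positive")
        if self.grid_n < 1:
            raise ParameterError("grid_n must be at least 1")
        # dt is fixed at 1 ms: other step sizes have not been validated for
        # the delay discretisation and are rejected rather than silently run.
        if self.dt != 1.0:
            raise ParameterError(f"dt is fixed at 1 ms, got {self.dt}")
        if self.gain_e < 0 or self.gain_i < 0:
            raise ParameterError("synaptic gains must be non-negative; the sign of "
                                 "inhibition is carried by the connection map")
        if self.psp_rise_e >= self.psp_decay_e or self.psp_rise_i >= self.psp_decay_i:
            raise ParameterError("PSP rise time constant must be smaller than decay")
        for counts in (self.neurons_e_per_layer, self.neurons_i_per_layer):
            if len(counts) != N_LAYERS:
                raise ParameterError(f"neuron counts must list {N_LAYERS} layers")
            if any(c < 0 for c in counts):
                raise ParameterError("neuron counts must be non-negative")

    @property
    def v_vertical(self) -> float:
        """Inter-laminar conduction speed (m/s)."""
        if self.speed_vertical is not None:
            return self.speed_vertical
        return 1.2 * self.speed_horizontal

    def resting_potential(self, pop: int) -> float:
        return self.resting_potential_e if pop == 0 else self.resting_potential_i

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["neurons_e_per_layer"] = list(self.neurons_e_per_layer)
        d["neurons_i_per_layer"] = list(self.neurons_i_per_layer)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        for key in ("neurons_e_per_layer", "neurons_i_per_layer"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        """Short stable hash of the parameter set, for run provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
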