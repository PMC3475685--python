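"""Laminar continuum dynamics: population state and the time-stepping core.

Each of the five cortical layers is a square grid of elements holding one
excitatory and one inhibitory population.  A step of the integrator executes
the model's four components in order:

1. *Spike generation* — a sigmoid maps each population's membrane potential
   to an average firing rate.
2. *Spike propagation* — rates travel to their targets with finite conduction
   delays; within a layer they spread laterally with an exponentially
   decaying, unit-sum weight kernel, while interlaminar connections couple
   vertically aligned elements only (centimetre-scale rule).
3. *Postsynaptic potential generation* — afferent rates are convolved with a
   causal difference-of-exponentials PSP kernel whose peak amplitude is the
   synaptic gain (V per afferent spike).
4. *Membrane aggregation* — each population's potential relaxes with
   first-order dynamics toward its resting potential plus the net PSP drive
   (excitatory depolarising, inhibitory hyperpolarising).

Lateral propagation uses circular (toroidal) convolution evaluated in the
frequency domain, with the firing-rate history kept in a ring buffer deep
enough for the longest conduction delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .connectome import ConnectionMap, default_connection_map
from .exceptions import ConfigError, InstabilityError, ParameterError
from .params import LAYERS, ModelParams, layer_index
from .stimulus import StimulusFields, StimulusProtocol, build_stimulus

#: Abort threshold: a departure from rest beyond this is far outside any
#: physiological value and marks numerical blow-up.
INSTABILITY_LIMIT_MV = 50.0


# ---------------------------------------------------------------------------
# component 1: spike generation
# ---------------------------------------------------------------------------

def firing_rate(potential, params: ModelParams):
    """Population firing rate (spikes/s) for a membrane potential (mV).

    Sigmoid activation: ``qmax / (1 + exp(-(V - theta) / slope))``; half the
    maximum rate at the threshold ``theta``, saturating at ``qmax``.
    """
    v = np.asarray(potential, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InstabilityError("non-finite membrane potential passed to firing_rate")
    return params.sigmoid_qmax / (1.0 + np.exp(-(v - params.sigmoid_theta)
                                               / params.sigmoid_slope))


# ---------------------------------------------------------------------------
# component 2: spike propagation
# ---------------------------------------------------------------------------

def conduction_delay(source_pos, target_pos, params: ModelParams) -> int:
    """Conduction delay in whole integration steps between two elements.

    Positions are ``(layer_index, row, col)`` grid coordinates.  The lateral
    leg travels at ``speed_horizontal``, the vertical leg at the interlaminar
    speed; the combined travel time is rounded to the nearest step with a
    floor of one step (minimum synaptic latency).  Lateral distance is the
    torus minimum-image distance, matching the propagation kernel.
    """
    (sl, si, sj), (tl, ti, tj) = source_pos, target_pos
    n = params.grid_n
    for (i, j) in ((si, sj), (ti, tj)):
        if not (0 <= i < n and 0 <= j < n):
            raise ConfigError(f"element ({i}, {j}) outside the {n}x{n} grid")
    di = min(abs(si - ti), n - abs(si - ti))
    dj = min(abs(sj - tj), n - abs(sj - tj))
    lateral_mm = math.hypot(di, dj) * params.element_spacing
    vertical_mm = abs(sl - tl) * params.layer_spacing
    # mm / (m/s) = ms
    travel_ms = lateral_mm / params.speed_horizontal + vertical_mm / params.v_vertical
    return max(1, int(round(travel_ms / params.dt)))


def lateral_kernel(params: ModelParams, pop: int):
    """Toroidal lateral weight kernel and per-offset delays for one source kind.

    Returns ``(weights, delays)``, both ``(n, n)`` arrays indexed by offset
    from the source with wrap-around.  Weights decay exponentially with the
    minimum-image distance on the scale ``range_e``/``range_i``, are cut off
    at three times that range, and are normalised to unit sum so that synapse
    counts remain the sole strength scaling.  Delays are the lateral travel
    times rounded to whole steps, floored at one.
    """
    n = params.grid_n
    rng_mm = params.range_e if pop == 0 else params.range_i
    idx = np.arange(n)
    off = np.minimum(idx, n - idx)  # minimum-image offset magnitude
    dist = np.hypot(off[:, None], off[None, :]) * params.element_spacing
    w = np.where(dist <= 3.0 * rng_mm, np.exp(-dist / rng_mm), 0.0)
    w /= w.sum()
    delays = np.maximum(1, np.rint(dist / params.speed_horizontal / params.dt)
                        .astype(int))
    return w, delays


# ---------------------------------------------------------------------------
# component 3: PSP generation
# ---------------------------------------------------------------------------

def _psp_peak_factor(rise: float, decay: float) -> float:
    """Peak value of the unnormalised kernel ``exp(-t/decay) - exp(-t/rise)``."""
    t_peak = math.log(decay / rise) * rise * decay / (decay - rise)
    return math.exp(-t_peak / decay) - math.exp(-t_peak / rise)


def psp_kernel(t, rise: float, decay: float, gain: float):
    """Causal difference-of-exponentials PSP kernel.

    ``t`` in ms; ``rise`` must be smaller than ``decay``.  The kernel is zero
    for negative times, unimodal, and normalised so its peak equals ``gain``
    (the peak postsynaptic potential per afferent spike, in V/spike).
    """
    if not 0 < rise < decay:
        raise ParameterError(f"PSP kernel requires 0 < rise < decay, got "
                             f"rise={rise}, decay={decay}")
    t = np.asarray(t, dtype=float)
    kappa = _psp_peak_factor(rise, decay)
    out = np.where(t >= 0, (np.exp(-np.clip(t, 0, None) / decay)
                            - np.exp(-np.clip(t, 0, None) / rise)) / kappa, 0.0)
    return gain * out


# ---------------------------------------------------------------------------
# component 4: membrane aggregation
# ---------------------------------------------------------------------------

def aggregate_membrane(potential, drive_mv, rest: float, tau_m: float,
                       dt: float):
    """One exact first-order relaxation step of the membrane potential.

    The potential relaxes toward ``rest + drive`` with time constant
    ``tau_m`` (drive held constant over the step):
    ``V <- rest + D + (V - rest - D) * exp(-dt / tau_m)``.
    """
    decay = math.exp(-dt / tau_m)
    target = rest + drive_mv
    return target + (potential - target) * decay


# ---------------------------------------------------------------------------
# state and compiled network
# ---------------------------------------------------------------------------

@dataclass
class CortexState:
    """Full dynamical state of the laminar sheet.

    Arrays are indexed ``(layer, population, row, col)``; the firing-rate
    history ring buffer and its 2-D real FFT are kept in step with the
    current time for delayed lateral propagation.
    """

    membrane_potential: np.ndarray      # (5, 2, n, n) mV
    rate_history: np.ndarray            # (depth, 5, 2, n, n) spikes/s
    rate_history_fft: np.ndarray        # (depth, 5, 2, n, n//2+1) complex
    psp_x: np.ndarray                   # (2 classes, 2 filters, 5, 2, n, n)
    step_index: int = 0

    @property
    def time(self) -> float:
        return float(self.step_index)

    @property
    def firing_rate(self) -> np.ndarray:
        """Rates generated at the most recent step."""
        depth = self.rate_history.shape[0]
        return self.rate_history[(self.step_index - 1) % depth]

    def copy(self) -> "CortexState":
        return CortexState(self.membrane_potential.copy(), self.rate_history.copy(),
                           self.rate_history_fft.copy(), self.psp_x.copy(),
                           self.step_index)


class LaminarCortexModel:
    """Compiled laminar network: kernels, delays and synapse-count tables.

    Construction validates the parameters and connection map and precomputes
    everything the per-step update needs; :meth:`step` then advances a
    :class:`CortexState` by one millisecond.
    """

    def __init__(self, params: ModelParams, connection_map: ConnectionMap | None = None):
        self.params = params
        self.connection_map = connection_map if connection_map is not None \
            else default_connection_map()
        n = params.grid_n
        nl = len(LAYERS)

        # lateral kernels split by delay group, FFT'd once
        self._lat_delays = []           # per source pop: (n_d,) int
        self._lat_kernel_fft = []       # per source pop: (n_d, n, n//2+1)
        max_delay = 1
        for pop in (0, 1):
            w, d = lateral_kernel(params, pop)
            uniq = np.unique(d[w > 0])
            kf = np.stack([np.fft.rfft2(np.where(d == du, w, 0.0)) for du in uniq])
            self._lat_delays.append(uniq.astype(int))
            self._lat_kernel_fft.append(kf)
            max_delay = max(max_delay, int(uniq.max()))

        # synapse-count tables
        self._within_counts = np.zeros((2, nl, 2))   # (src pop, layer, tgt pop)
        self._inter: list[tuple[int, int, int, int, float, int]] = []
        for e in self.connection_map.intracortical():
            sl, tl = layer_index(e.source_layer), layer_index(e.target_layer)
            sp, tp = ("E", "I").index(e.source_pop), ("E", "I").index(e.target_pop)
            if sl == tl:
                self._within_counts[sp, tl, tp] += e.count
            else:
                delay = max(1, int(round(abs(sl - tl) * params.layer_spacing
                                         / params.v_vertical / params.dt)))
                self._inter.append((sl, sp, tl, tp, e.count, delay))
                max_delay = max(max_delay, delay)
        self._thal_counts = np.zeros((nl, 2))
        self._cc_counts = np.zeros((nl, 2))
        for e in self.connection_map.external("thalamic"):
            self._thal_counts[layer_index(e.target_layer),
                              ("E", "I").index(e.target_pop)] += e.count
        for e in self.connection_map.external("cortico-cortical"):
            self._cc_counts[layer_index(e.target_layer),
                            ("E", "I").index(e.target_pop)] += e.count

        self.buffer_depth = max_delay + 1

        # PSP filter constants (exact exponential update; x in ms * spikes/s)
        p = params
        self._psp_const = []
        for rise, decay, gain in ((p.psp_rise_e, p.psp_decay_e, p.gain_e),
                                  (p.psp_rise_i, p.psp_decay_i, p.gain_i)):
            a_d, a_r = math.exp(-p.dt / decay), math.exp(-p.dt / rise)
            self._psp_const.append({
                "a": (a_d, a_r),
                "b": (decay * (1.0 - a_d), rise * (1.0 - a_r)),
                "scale": gain / _psp_peak_factor(rise, decay),
            })
        self._rest = np.array([p.resting_potential_e, p.resting_potential_i])
        self._tau_m = np.array([p.membrane_time_constant_e, p.membrane_time_constant_i])
        self._mem_decay = np.exp(-p.dt / self._tau_m)[None, :, None, None]
        self._rest_b = self._rest[None, :, None, None]

    # -- state construction -------------------------------------------------
    def initial_state(self) -> CortexState:
        """Resting state: potentials at rest, buffers primed with resting rates."""
        p = self.params
        n, nl, d = p.grid_n, len(LAYERS), self.buffer_depth
        v = np.broadcast_to(self._rest_b, (nl, 2, n, n)).copy()
        q0 = firing_rate(v, p)
        hist = np.broadcast_to(q0, (d, nl, 2, n, n)).copy()
        hist_fft = np.fft.rfft2(hist, axes=(-2, -1))
        psp_x = np.zeros((2, 2, nl, 2, n, n))
        return CortexState(v, hist, np.ascontiguousarray(hist_fft), psp_x, 0)

    # -- spike propagation over the delayed history --------------------------
    def _lateral_fields(self, state: CortexState, pop: int) -> np.ndarray:
        """Delayed lateral propagation of one source population kind.

        Returns the ``(5, n, n)`` field of afferent rate per layer: the
        circular convolution of each delay-group kernel with the firing-rate
        field recorded that many steps ago, summed over delay groups.
        """
        n = self.params.grid_n
        depth = state.rate_history.shape[0]
        t = state.step_index
        idx = (t - self._lat_delays[pop]) % depth
        g = state.rate_history_fft[idx, :, pop]        # (n_d, 5, n, kf)
        acc = np.einsum("dxk,dlxk->lxk", self._lat_kernel_fft[pop], g)
        return np.fft.irfft2(acc, s=(n, n), axes=(-2, -1))

    def propagate_spikes(self, state: CortexState, stimuli: StimulusFields
                         ) -> tuple[np.ndarray, np.ndarray]:
        """Total excitatory and inhibitory afferent rate per target population.

        Each returned array has shape ``(5, 2, n, n)`` (layer, target pop,
        grid); entries are synapse-count-weighted sums of delayed source
        rates plus the external thalamic and cortico-cortical streams (which
        count as excitatory afferents).
        """
        n = self.params.grid_n
        depth = state.rate_history.shape[0]
        t = state.step_index
        lat_e = self._lateral_fields(state, 0)
        lat_i = self._lateral_fields(state, 1)
        # within_counts[src pop] is (layer, tgt pop); aff arrays are
        # (layer, tgt pop, n, n)
        aff_e = np.ascontiguousarray(
            self._within_counts[0][:, :, None, None] * lat_e[:, None])
        aff_i = np.ascontiguousarray(
            self._within_counts[1][:, :, None, None] * lat_i[:, None])
        for (sl, sp, tl, tp, cnt, delay) in self._inter:
            src = state.rate_history[(t - delay) % depth, sl, sp]
            if sp == 0:
                aff_e[tl, tp] += cnt * src
            else:  # pragma: no cover - excluded by map invariant
                aff_i[tl, tp] += cnt * src
        cc = stimuli.cortico_at(t)
        for lay in range(len(LAYERS)):
            th = stimuli.thalamic_at(t, lay)
            for tp in (0, 1):
                aff_e[lay, tp] += self._thal_counts[lay, tp] * th \
                    + self._cc_counts[lay, tp] * cc
        return aff_e, aff_i

    # -- one integration step ------------------------------------------------
    def step(self, state: CortexState, stimuli: StimulusFields) -> CortexState:
        """Advance the state by one step (in place) and return it.

        Executes spike generation, propagation, PSP convolution update and
        membrane aggregation, in that order.  Deterministic given the state
        and stimulus series.
        """
        p = self.params
        t = state.step_index
        depth = state.rate_history.shape[0]

        v = state.membrane_potential
        if not np.all(np.isfinite(v)):
            bad = np.argwhere(~np.isfinite(v))[0]
            raise InstabilityError(
                f"non-finite membrane potential at t={t * p.dt:.0f} ms, layer "
                f"{LAYERS[bad[0]]}, pop {'EI'[bad[1]]}, element "
                f"({bad[2]}, {bad[3]})", time_ms=t * p.dt)

        # 1. spike generation, pushed into the delay ring
        q = firing_rate(v, p)
        idx = t % depth
        state.rate_history[idx] = q
        state.rate_history_fft[idx] = np.fft.rfft2(q, axes=(-2, -1))

        # 2. spike propagation through the delayed history
        aff_e, aff_i = self.propagate_spikes(state, stimuli)

        # 3. PSP kernel convolution (two first-order filters per class)
        drives = []
        for cls, aff in ((0, aff_e), (1, aff_i)):
            c = self._psp_const[cls]
            x = state.psp_x[cls]
            x[0] = x[0] * c["a"][0] + aff * c["b"][0]
            x[1] = x[1] * c["a"][1] + aff * c["b"][1]
            drives.append(c["scale"] * (x[0] - x[1]))
        net_drive = drives[0] - drives[1]

        # 4. membrane aggregation (exact first-order relaxation)
        target = self._rest_b + net_drive
        state.membrane_potential = target + (v - target) * self._mem_decay

        dev = np.abs(state.membrane_potential - self._rest_b).max()
        if dev > INSTABILITY_LIMIT_MV:
            raise InstabilityError(
                f"membrane potential departed rest by {dev:.1f} mV "
                f"(> {INSTABILITY_LIMIT_MV:.0f} mV) at t={(t + 1) * p.dt:.0f} ms; "
                f"the run is unstable at these gains", time_ms=(t + 1) * p.dt)

        state.step_index = t + 1
        return state


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Complete specification of one simulation run."""

    params: ModelParams = field(default_factory=ModelParams)
    connection_map: ConnectionMap | None = None
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    warmup_ms: float = 60000.0
    stim_ms: float = 20000.0
    seed: int = 0
    record_line: bool = False

    def __post_init__(self):
        if self.warmup_ms < 0 or self.stim_ms < 0:
            raise ConfigError("epoch durations must be non-negative")
        if self.stim_ms > 0 and self.warmup_ms <= 0 and self.protocol.kind not in (
                "spontaneous", "silent"):
            raise ConfigError("stimulation cannot start before the warm-up epoch")

    @property
    def n_steps(self) -> int:
        return int(round((self.warmup_ms + self.stim_ms) / self.params.dt))


@dataclass
class SimulationResult:
    """Recorded traces of a run, at 1 kHz, with provenance metadata.

    ``potentials`` holds the central-element membrane potential of every
    (layer, population) pair at each step; ``line`` optionally holds the
    central row of every layer (for spatial/CSD analyses).
    """

    potentials: np.ndarray              # (T, 5, 2) mV
    dt: float                           # ms
    warmup_ms: float
    stim_ms: float
    seed: int
    params: ModelParams
    protocol_kind: str
    params_digest: str
    line: np.ndarray | None = None      # (T, 5, 2, n) mV

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.potentials.shape[0]) * self.dt

    @property
    def sample_rate(self) -> float:
        return 1000.0 / self.dt

    def element_potentials(self) -> np.ndarray:
        """Central-element potential per layer: count-weighted E/I average."""
        ne = np.asarray(self.params.neurons_e_per_layer)
        ni = np.asarray(self.params.neurons_i_per_layer)
        return (self.potentials[:, :, 0] * ne + self.potentials[:, :, 1] * ni) \
            / (ne + ni)

    def lfp(self) -> np.ndarray:
        """LFP trace: neuron-count-weighted average across layers."""
        from .analysis import lfp_aggregate
        ne = np.asarray(self.params.neurons_e_per_layer)
        ni = np.asarray(self.params.neurons_i_per_layer)
        return lfp_aggregate(self.potentials[:, :, 0], self.potentials[:, :, 1],
                             ne, ni)

    def _window(self, end_step: int, window: int) -> slice:
        if end_step < window:
            raise ConfigError(f"epoch too short for a {window}-sample analysis window")
        return slice(end_step - window, end_step)

    def spont_window(self, window: int = 1024) -> slice:
        """Final ``window`` samples of the spontaneous (warm-up) epoch."""
        return self._window(int(round(self.warmup_ms / self.dt)), window)

    def stim_window(self, window: int = 1024) -> slice:
        """Final ``window`` samples of the stimulation epoch."""
        return self._window(self.potentials.shape[0], window)


def run_simulation(config: RunConfig) -> SimulationResult:
    """Run the full schedule of a configuration and record the central traces.

    The run executes the warm-up epoch (spontaneous input) followed by the
    stimulation epoch defined by the protocol, both at the fixed 1 ms step.
    Identical configurations and seeds produce identical results.
    """
    model = LaminarCortexModel(config.params, config.connection_map)
    p = config.params
    n = p.grid_n
    c = n // 2
    stimuli = build_stimulus(config.protocol, config.warmup_ms, config.stim_ms,
                             p.dt, n, config.seed)
    n_steps = config.n_steps
    state = model.initial_state()
    potentials = np.empty((n_steps, len(LAYERS), 2))
    line = np.empty((n_steps, len(LAYERS), 2, n)) if config.record_line else None
    for t in range(n_steps):
        state = model.step(state, stimuli)
        potentials[t] = state.membrane_potential[:, :, c, c]
        if line is not None:
            line[t] = state.membrane_potential[:, :, c, :]
    return SimulationResult(potentials=potentials, dt=p.dt,
                            warmup_ms=config.warmup_ms, stim_ms=config.stim_ms,
                            seed=config.seed, params=p,
                            protocol_kind=config.protocol.kind,
                            params_digest=p.digest(), line=line)
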