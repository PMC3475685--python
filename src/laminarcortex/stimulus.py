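"""External afferent spike-rate generation.

Two afferent streams drive the model: thalamic (LGN) input, which carries the
visual stimulus, and cortico-cortical input from other areas, modelled as
low-amplitude white noise.  Three stimulation states are supported, mirroring
the experimental protocols: spontaneous activity (small-amplitude white
noise), constant visual stimulation (large-amplitude white noise) and
intermittent light stimulation (recurring Gaussian pulses of spike rate).
A transient point source can additionally be injected into chosen elements
of one layer.

Thalamic and cortico-cortical input is spatially uniform across elements
(the protocols carry no retinotopic structure); only the point source breaks
spatial symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError
from .params import layer_index

PROTOCOL_KINDS = ("spontaneous", "constant_visual", "intermittent_light",
                  "point_source", "silent")


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulation protocol: noise levels and pulse/point-source shape.

    Rates are in spikes/s, times in ms.  ``noise_mean``/``noise_amplitude``
    describe the thalamic stream during the stimulation epoch; the warm-up
    epoch always uses the spontaneous levels.  The defaults for "small" and
    "large" amplitude noise are calibration stand-ins exposed here.
    """

    kind: str = "spontaneous"
    # thalamic white noise, spontaneous epoch
    spont_mean: float = 5.0
    spont_amplitude: float = 2.0
    # thalamic white noise, constant-visual-stimulation epoch
    noise_mean: float = 30.0
    noise_amplitude: float = 20.0
    # intermittent light: recurring Gaussian pulses on top of spontaneous noise
    pulse_peak: float = 30.0          # spikes/s
    pulse_sd: float = 6.25            # ms
    pulse_period: float = 100.0       # ms (10 Hz)
    # transient point source
    source_elements: tuple[tuple[int, int], ...] = ()
    source_rate: float = 100.0        # spikes/s
    source_duration: float = 20.0     # ms
    source_layer: str = "IV"
    # cortico-cortical background noise (always on)
    background_mean: float = 5.0
    background_amplitude: float = 2.0

    def __post_init__(self):
        if self.kind not in PROTOCOL_KINDS:
            raise ConfigError(f"unknown protocol kind {self.kind!r}")
        for name in ("spont_mean", "spont_amplitude", "noise_mean", "noise_amplitude",
                     "pulse_peak", "source_rate", "background_mean",
                     "background_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.pulse_sd <= 0:
            raise ConfigError("pulse_sd must be positive")
        if self.pulse_period <= 4 * self.pulse_sd:
            raise ConfigError("pulse_period must exceed 4 x pulse_sd so pulses are "
                              "well separated")
        if self.source_duration < 0:
            raise ConfigError("source_duration must be non-negative")


def white_noise_train(mean: float, amplitude: float, duration: float, dt: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Uniform white-noise spike-rate series, clipped at zero.

    Values are ``mean + U(-amplitude, +amplitude)`` per step.  Clipping at
    zero slightly biases the sample mean upward when ``amplitude > mean``.
    """
    if mean < 0 or amplitude < 0:
        raise ConfigError("mean and amplitude must be non-negative")
    n = int(round(duration / dt))
    series = mean + rng.uniform(-amplitude, amplitude, size=n)
    np.clip(series, 0.0, None, out=series)
    return series


def gaussian_pulse_train(peak: float, sd: float, period: float, duration: float,
                         dt: float) -> np.ndarray:
    """Deterministic train of Gaussian spike-rate pulses.

    Pulse centres sit at ``period/2, 3*period/2, ...`` so every pulse is
    complete within the series.  Local maxima equal ``peak``.
    """
    if sd <= 0 or period <= 0:
        raise ConfigError("sd and period must be positive")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    # offset from the nearest pulse centre (centres at period/2, 3*period/2, ...)
    offset = (t % period) - period / 2.0
    return peak * np.exp(-0.5 * (offset / sd) ** 2)


def point_source(elements, rate: float, onset: float, duration: float,
                 baseline: np.ndarray, grid_n: int, dt: float = 1.0) -> np.ndarray:
    """Thalamic rate field over time: a transient source on listed elements.

    Returns an array of shape ``(len(baseline), grid_n, grid_n)`` equal to the
    (spatially uniform) baseline series everywhere, plus ``rate`` on the
    listed elements during ``[onset, onset + duration)``.
    """
    for (i, j) in elements:
        if not (0 <= i < grid_n and 0 <= j < grid_n):
            raise ConfigError(f"point-source element ({i}, {j}) outside the "
                              f"{grid_n}x{grid_n} grid")
    n = len(baseline)
    field_ = np.broadcast_to(np.asarray(baseline)[:, None, None],
                             (n, grid_n, grid_n)).copy()
    i0 = int(round(onset / dt))
    i1 = int(round((onset + duration) / dt))
    i0, i1 = max(i0, 0), min(i1, n)
    for (i, j) in elements:
        field_[i0:i1, i, j] += rate
    return field_


def central_elements(grid_n: int, k: int = 4) -> tuple[tuple[int, int], ...]:
    """The ``k`` central elements of an ``grid_n`` x ``grid_n`` grid.

    For the default ``k = 4`` this is the 2x2 block around the centre.
    """
    c = grid_n // 2
    if k == 4:
        return ((c - 1, c - 1), (c - 1, c), (c, c - 1), (c, c))
    if k == 1:
        return ((c, c),)
    raise ConfigError("central_elements supports k in {1, 4}")


@dataclass(frozen=True)
class PointSourceSpec:
    """Sparse description of a transient point source in one layer."""

    layer: int                 # layer index receiving the source
    mask: np.ndarray           # (n, n) boolean, driven elements
    rate: float                # spikes/s added on masked elements
    start: int                 # first active step (inclusive)
    stop: int                  # last active step (exclusive)


@dataclass
class StimulusFields:
    """Per-step afferent rate inputs for a run.

    ``thalamic`` and ``cortico`` are spatially uniform ``(T,)`` series;
    ``point`` optionally adds a localized transient to one layer's thalamic
    drive (stored sparsely — a dense ``(T, n, n)`` field for a full run
    would be needlessly large).
    """

    thalamic: np.ndarray
    cortico: np.ndarray
    point: PointSourceSpec | None = None

    def thalamic_at(self, step: int, layer: int):
        """Thalamic rate for ``layer`` at ``step``: scalar or (n, n) field."""
        base = self.thalamic[step]
        p = self.point
        if p is not None and p.layer == layer and p.start <= step < p.stop:
            return base + p.rate * p.mask
        return base

    def cortico_at(self, step: int) -> float:
        return self.cortico[step]


def build_stimulus(protocol: StimulusProtocol, warmup_ms: float, stim_ms: float,
                   dt: float, grid_n: int, seed) -> StimulusFields:
    """Assemble the full-run thalamic and cortico-cortical input series.

    The warm-up epoch always uses the spontaneous noise levels; the
    stimulation epoch switches according to the protocol kind at exactly
    ``t = warmup_ms``.  The thalamic and cortico-cortical streams draw from
    independent RNG child streams of ``seed``, so changing one leaves the
    other's realisation untouched.
    """
    ss = np.random.SeedSequence(seed)
    thal_ss, cc_ss = ss.spawn(2)
    thal_rng = np.random.default_rng(thal_ss)
    cc_rng = np.random.default_rng(cc_ss)
    total_ms = warmup_ms + stim_ms
    n_total = int(round(total_ms / dt))

    cortico = white_noise_train(protocol.background_mean, protocol.background_amplitude,
                                total_ms, dt, cc_rng)
    if protocol.kind == "silent":
        return StimulusFields(np.zeros(n_total), np.zeros(n_total))

    warm = white_noise_train(protocol.spont_mean, protocol.spont_amplitude,
                             warmup_ms, dt, thal_rng)
    if protocol.kind == "spontaneous":
        stim = white_noise_train(protocol.spont_mean, protocol.spont_amplitude,
                                 stim_ms, dt, thal_rng)
        thal: np.ndarray = np.concatenate([warm, stim])
    elif protocol.kind == "constant_visual":
        stim = white_noise_train(protocol.noise_mean, protocol.noise_amplitude,
                                 stim_ms, dt, thal_rng)
        thal = np.concatenate([warm, stim])
    elif protocol.kind == "intermittent_light":
        base = white_noise_train(protocol.spont_mean, protocol.spont_amplitude,
                                 stim_ms, dt, thal_rng)
        pulses = gaussian_pulse_train(protocol.pulse_peak, protocol.pulse_sd,
                                      protocol.pulse_period, stim_ms, dt)
        thal = np.concatenate([warm, base + pulses])
    elif protocol.kind == "point_source":
        base = white_noise_train(protocol.spont_mean, protocol.spont_amplitude,
                                 stim_ms, dt, thal_rng)
        thal = np.concatenate([warm, base])
        elements = protocol.source_elements or central_elements(grid_n)
        mask = np.zeros((grid_n, grid_n), dtype=bool)
        for (i, j) in elements:
            if not (0 <= i < grid_n and 0 <= j < grid_n):
                raise ConfigError(f"point-source element ({i}, {j}) outside the "
                                  f"{grid_n}x{grid_n} grid")
            mask[i, j] = True
        start = int(round(warmup_ms / dt))
        stop = start + int(round(protocol.source_duration / dt))
        pt = PointSourceSpec(layer=layer_index(protocol.source_layer), mask=mask,
                             rate=protocol.source_rate, start=start, stop=stop)
        return StimulusFields(thal, cortico, pt)
    else:  # pragma: no cover - kinds validated in __post_init__
        raise ConfigError(f"unhandled protocol kind {protocol.kind!r}")
    return StimulusFields(thal, cortico)
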