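"""LFP aggregation, spectral analysis and current source density.

The measurement stack mirrors standard laminar electrophysiology practice:
the LFP is the neuron-count-weighted average of population membrane
potentials, its power spectrum is the single-sided FFT periodogram of a
mean-removed analysis window (1.024 s by default), band powers summarise
gamma (30-100 Hz) and sub-gamma (5-20 Hz) activity, a log-log regression
estimates the 1/f^gamma background exponent, and the one-dimensional CSD is
the negative scaled second spatial difference of a laminar potential
profile, optionally smoothed with a three-point Hamming filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigError


@dataclass(frozen=True)
class SpectrumResult:
    """Single-sided power spectrum on a regular frequency grid."""

    frequencies: np.ndarray     # Hz, 0 .. Nyquist
    power: np.ndarray           # mV^2 per bin
    n_samples: int
    sample_rate: float          # Hz
    n_runs_averaged: int = 1

    def __post_init__(self):
        f, p = np.asarray(self.frequencies), np.asarray(self.power)
        if f.shape != p.shape:
            raise ConfigError("frequency and power grids must match")
        if len(f) >= 2 and not np.all(np.diff(f) > 0):
            raise ConfigError("frequencies must be strictly increasing")
        if np.any(p < 0):
            raise ConfigError("power must be non-negative")

    @property
    def nyquist(self) -> float:
        return self.sample_rate / 2.0

    @property
    def resolution(self) -> float:
        return self.sample_rate / self.n_samples


@dataclass(frozen=True)
class CSDProfile:
    """One-dimensional current source density at interior profile points."""

    positions: np.ndarray       # mm, depth/offset of interior points
    values: np.ndarray          # A/m^3; positive marks a current source
    sigma: float                # S/m, cortical conductivity
    spacing: float              # mm between adjacent input points


def lfp_aggregate(potentials_e, potentials_i, counts_e, counts_i) -> np.ndarray:
    """Neuron-count-weighted LFP from per-layer E and I population potentials.

    Per layer, the element potential is ``(N_e V_e + N_i V_i) / (N_e + N_i)``;
    the LFP is the total-count-weighted average of the element potentials
    across layers.  Inputs may carry a leading time axis (layers last).
    """
    ve, vi = np.asarray(potentials_e, float), np.asarray(potentials_i, float)
    ne, ni = np.asarray(counts_e, float), np.asarray(counts_i, float)
    totals = ne + ni
    if np.all(totals == 0):
        raise ConfigError("all neuron counts are zero: LFP average undefined")
    element = (ne * ve + ni * vi) / np.where(totals > 0, totals, 1.0)
    return (element * totals).sum(axis=-1) / totals.sum()


def power_spectrum(trace, sample_rate: float, window_samples: int = 1024
                   ) -> SpectrumResult:
    """Single-sided FFT power spectrum of the final window of a trace.

    The window mean (DC) is removed before transforming; no taper is applied.
    Power is scaled so the sum over non-DC bins equals the variance of the
    windowed trace (Parseval).  Frequency resolution is
    ``sample_rate / window_samples`` (~0.977 Hz at the 1024-sample, 1 kHz
    default).
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ConfigError("power_spectrum expects a 1-D trace")
    if window_samples > x.size:
        raise ConfigError(f"window of {window_samples} samples exceeds trace "
                          f"length {x.size}")
    w = x[-window_samples:]
    w = w - w.mean()
    n = window_samples
    spec = np.fft.rfft(w)
    power = np.abs(spec) ** 2 / n**2
    # fold the negative frequencies onto the positive bins
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    return SpectrumResult(freqs, power, n, float(sample_rate))


def average_spectra(spectra) -> SpectrumResult:
    """Arithmetic per-bin mean of spectra on identical frequency grids."""
    spectra = list(spectra)
    if not spectra:
        raise ConfigError("average_spectra needs at least one spectrum")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.frequencies.shape != ref.frequencies.shape or \
                not np.allclose(s.frequencies, ref.frequencies):
            raise ConfigError("spectra have mismatched frequency grids")
    mean_power = np.mean([s.power for s in spectra], axis=0)
    n_runs = sum(s.n_runs_averaged for s in spectra)
    return replace(ref, power=mean_power, n_runs_averaged=n_runs)


def band_power(spectrum: SpectrumResult, f_lo: float, f_hi: float) -> float:
    """Mean power over bins with ``f_lo <= f < f_hi``."""
    if not 0 <= f_lo < f_hi <= spectrum.nyquist:
        raise ConfigError(f"invalid band [{f_lo}, {f_hi}) for Nyquist "
                          f"{spectrum.nyquist} Hz")
    mask = (spectrum.frequencies >= f_lo) & (spectrum.frequencies < f_hi)
    if not mask.any():
        raise ConfigError(f"band [{f_lo}, {f_hi}) contains no frequency bins")
    return float(spectrum.power[mask].mean())


def fit_power_law(spectrum: SpectrumResult, f_lo: float, f_hi: float) -> float:
    """Exponent gamma of a ``1/f^gamma`` fit over ``[f_lo, f_hi]``.

    Ordinary least squares of log power against log frequency; bins with
    non-positive power are excluded, and at least 10 usable bins are
    required.  Pure ``f^-2`` data yields exactly ``gamma = 2``.
    """
    mask = (spectrum.frequencies >= f_lo) & (spectrum.frequencies <= f_hi) \
        & (spectrum.frequencies > 0) & (spectrum.power > 0)
    if mask.sum() < 10:
        raise ConfigError("power-law fit needs at least 10 bins with positive "
                          f"power in [{f_lo}, {f_hi}] Hz, found {int(mask.sum())}")
    slope, _ = np.polyfit(np.log(spectrum.frequencies[mask]),
                          np.log(spectrum.power[mask]), 1)
    return float(-slope)


def power_law_prediction(spectrum: SpectrumResult, f_lo: float, f_hi: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Fitted ``1/f^gamma`` power at each bin of the fit band.

    Returns ``(frequencies, predicted power)`` for the bins used by
    :func:`fit_power_law`'s regression, for peak-excess classification.
    """
    mask = (spectrum.frequencies >= f_lo) & (spectrum.frequencies <= f_hi) \
        & (spectrum.frequencies > 0) & (spectrum.power > 0)
    if mask.sum() < 10:
        raise ConfigError("power-law fit needs at least 10 bins with positive power")
    logf = np.log(spectrum.frequencies[mask])
    slope, intercept = np.polyfit(logf, np.log(spectrum.power[mask]), 1)
    return spectrum.frequencies[mask], np.exp(intercept + slope * logf)


def csd(potential_profile, sigma: float, h: float) -> CSDProfile:
    """Standard one-dimensional current source density.

    ``CSD_i = -sigma * (phi_{i+1} - 2 phi_i + phi_{i-1}) / h^2`` at the
    interior points of an equally spaced profile.  Inputs are in mV and mm;
    the result is in SI units (A/m^3), with positive values marking current
    sources.  Endpoints are dropped (the second difference is undefined
    there).  The profile may carry a leading time axis (space last).
    """
    phi = np.asarray(potential_profile, dtype=float)
    if phi.shape[-1] < 3:
        raise ConfigError("CSD needs a profile of at least 3 points")
    if h <= 0:
        raise ConfigError("point spacing h must be positive")
    second_diff_mv = phi[..., 2:] - 2.0 * phi[..., 1:-1] + phi[..., :-2]
    # mV -> V (1e-3), mm^2 -> m^2 (1e-6): net factor 1e3
    values = -sigma * second_diff_mv * 1e-3 / (h * 1e-3) ** 2
    positions = (np.arange(phi.shape[-1] - 2) + 1) * h
    return CSDProfile(positions=positions, values=values, sigma=sigma, spacing=h)


#: Three-point Hamming weights (unit sum).
HAMMING_WEIGHTS = (0.23, 0.54, 0.23)


def hamming_smooth(profile) -> np.ndarray:
    """Three-point Hamming smoothing of a spatial profile.

    Interior points are replaced by the (0.23, 0.54, 0.23)-weighted average
    of themselves and their neighbours; endpoints pass through unchanged.
    The profile may carry a leading time axis (space last).
    """
    x = np.asarray(profile, dtype=float)
    if x.shape[-1] < 3:
        raise ConfigError("Hamming smoothing needs at least 3 points")
    w_side, w_mid = HAMMING_WEIGHTS[0], HAMMING_WEIGHTS[1]
    out = x.copy()
    out[..., 1:-1] = w_side * x[..., :-2] + w_mid * x[..., 1:-1] + w_side * x[..., 2:]
    return out


def detect_harmonics(spectrum: SpectrumResult, baseline: SpectrumResult,
                     min_prominence: float = 2.0, f_min: float = 2.0,
                     local_halfwidth: int = 10) -> list[float]:
    """Frequencies where stimulation raised power well above baseline.

    A bin is reported when the stimulated/baseline power ratio (i) exceeds
    ``min_prominence``, (ii) is a local maximum of the ratio, (iii) exceeds
    ``min_prominence`` times the local median of the ratio in a
    ``local_halfwidth``-bin neighbourhood (so a broadband power increase
    does not register as a comb of peaks), and (iv) lies at or above
    ``f_min`` (excluding DC and slow drift).  Zero-power baseline bins are
    floored at a small epsilon relative to the baseline maximum so the
    ratio stays finite.  Frequencies are returned sorted ascending.
    """
    if spectrum.frequencies.shape != baseline.frequencies.shape or \
            not np.allclose(spectrum.frequencies, baseline.frequencies):
        raise ConfigError("spectrum and baseline must share a frequency grid")
    base = baseline.power.copy()
    floor = max(base.max(), np.finfo(float).tiny) * 1e-12
    base = np.maximum(base, floor)
    ratio = spectrum.power / base
    freqs = spectrum.frequencies
    peaks = []
    for k in range(1, len(ratio) - 1):
        if freqs[k] < f_min:
            continue
        if not (ratio[k] >= min_prominence and ratio[k] > ratio[k - 1]
                and ratio[k] >= ratio[k + 1]):
            continue
        lo = max(1, k - local_halfwidth)
        hi = min(len(ratio), k + local_halfwidth + 1)
        neighbours = [ratio[j] for j in range(lo, hi) if abs(j - k) > 2]
        if neighbours and ratio[k] < min_prominence * np.median(neighbours):
            continue
        peaks.append(float(freqs[k]))
    return peaks
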