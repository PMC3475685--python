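# Model and methods

## The model

`laminarcortex` simulates a patch of primary visual cortex as five stacked
continuum (population mean-field) sheets, one per cortical lamina (I, II/III,
IV, V, VI).  Each sheet is a square grid of *elements*; at the centimetre
scale simulated here an element corresponds to one cortical column
(0.5 mm spacing by default).  Every element holds two neural populations,
excitatory (E) and inhibitory (I), each characterised by an average membrane
potential `V` (mV) and an average firing rate `Q` (spikes/s).  Individual
spikes are not simulated; populations interact through average afferent
spike rates.

One 1 ms step executes four components in order:

1. **Spike generation.**  `Q(V) = Q_max / (1 + exp(-(V - theta)/sigma))`,
   a sigmoid with half-activation at the threshold `theta` and ceiling
   `Q_max`.  Rates are therefore bounded in `[0, Q_max]` by construction.
2. **Spike propagation.**  Rates reach their targets after a conduction
   delay `d = max(1 step, round(lateral/v_h + vertical/v_v))`, with
   `v_h = 0.24 m/s` laterally and `v_v = 1.2 v_h` between laminae.  Within
   a layer, a source population's rate spreads laterally with weights
   `w(r) ∝ exp(-r / range)`, cut off at `3 × range` and normalised to unit
   sum, so synapse counts remain the only strength scaling and a uniform
   rate field propagates to exactly `count × rate`.  Between laminae only
   vertically aligned elements couple (the centimetre-scale rule: columns
   are vertical processing units).  The afferent rate of a target is the
   synapse-count-weighted sum over its connection-map entries plus the
   external thalamic and cortico-cortical streams.
3. **PSP generation.**  Each target population carries two synaptic filter
   banks (excitatory- and inhibitory-afferent).  The afferent rate is
   convolved with a causal difference-of-exponentials kernel
   `h(t) ∝ exp(-t/tau_decay) - exp(-t/tau_rise)`, normalised so its peak is
   the synaptic gain `G` — the peak PSP per afferent spike, in V/spike.
   The convolution is computed by two exact-exponential first-order filters
   (zero-order hold on the input), so the discrete impulse response matches
   the closed form exactly.
4. **Membrane aggregation.**  `V` relaxes toward
   `V_rest + drive_E - drive_I` with first-order dynamics of time constant
   `tau_m`, stepped with the exact exponential update.  Excitatory drive
   depolarises, inhibitory drive hyperpolarises.

The lateral boundary is toroidal (circular convolution), which removes edge
artefacts from the spectra of the recorded central element; a reflecting
boundary is not implemented.  The state equations above are this package's
reconstruction of the standard continuum-model forms; they are the
conventional choices for sigmoid rate functions, biexponential PSPs and RC
membranes in neural field modelling.

### Stability policy

If any population departs rest by more than 50 mV — far beyond any
physiological value — the run aborts with an `InstabilityError` carrying
the time and location.  Clipping instead would silently corrupt every
downstream spectrum.  In the seizure-like (large-gain) regime the bounded
limit cycles reach a few tens of mV; runs that exceed the diagnostic bound
are reported as failed cells by the sweep machinery rather than aborting a
whole sweep.

## Connectivity

The laminar connection map lists synapse counts from each source (layer ×
E/I, or the external categories `thalamic` and `cortico-cortical`) to each
target population.  Inhibitory sources project only within their own layer
(inhibition is local); thalamic afferents reach layers IV, V and VI only.
The shipped default map is a *structural stand-in*, not an anatomical
census: it encodes the canonical visual-cortex circuit — thalamic input
dominating layers IV and VI with a weak collateral to V, the excitatory
relay IV → II/III → V → VI → IV, within-layer E/I loops, and diffuse
cortico-cortical background onto every layer — with relative counts fixed
during calibration (below).  Layer IV carries stronger local feedforward
inhibition (E→I and I→E counts 450 vs 350/300 elsewhere), as expected for
the thalamorecipient lamina; this also makes the layer-IV-reduction
experiment behave sensibly, since halving layer-IV presynaptic output then
removes a large damping term.  The map round-trips losslessly through a
tab-separated text file and is fully user-editable.

## Stimulation

Visual input arrives as the thalamic stream: uniform across elements (the
protocols carry no retinotopic structure), drawn per step.  Protocols:

- *spontaneous*: uniform white noise, mean 5, amplitude 2 spikes/s;
- *constant visual stimulation*: mean 30, amplitude 20 spikes/s;
- *intermittent light*: spontaneous noise plus a deterministic train of
  Gaussian rate pulses (peak 30 spikes/s, SD 6.25 ms, period 100 ms =
  10 Hz);
- *point source*: 100 spikes/s onto the four central elements of layer IV
  for 20 ms at the end of the warm-up;
- *silent*: all inputs zero (testing).

Cortico-cortical input from unmodelled areas is always-on low-amplitude
white noise (mean 5, amplitude 2 spikes/s).  Noise is uniform
(`mean ± amplitude`), clipped at zero — the clip slightly biases the mean
upward when `amplitude > mean`.  The noise means and amplitudes are
calibration stand-ins exposed in the protocol config.  The thalamic and
cortico-cortical streams use independent child RNG streams of the run
seed, so either can be changed without perturbing the other's realisation.
The schedule is a 60 s spontaneous warm-up followed by 20 s of stimulation
(fully configurable; the tests and the acceptance script use shortened
schedules, 4–20 s warm-up, on a 10×10 grid — with spatially uniform input
the dynamics are independent of grid size, so this loses nothing but
spatial detail).

## Measurement stack

- Central-element membrane potentials of every (layer, population) pair are
  recorded at 1 kHz.  The *element potential* of a layer is the
  neuron-count-weighted E/I average `(N_e V_e + N_i V_i)/(N_e + N_i)`; the
  *LFP* is the total-count-weighted average of element potentials across
  layers.  Default counts per element: 80 % excitatory, layer totals
  2 000 (I), 30 000 (II/III), 30 000 (IV), 20 000 (V), 20 000 (VI) —
  stand-ins; only ratios matter.
- *Power spectra*: single-sided FFT periodogram of the mean-removed final
  1.024 s (1024 samples) of an epoch, no taper, scaled so the non-DC sum
  equals the window variance (Parseval).  Spectra are averaged across
  seeded runs before any classification; single-run periodogram bins carry
  chi-squared scatter that threshold rules misread.
- *Band powers*: mean bin power over gamma (30–100 Hz) and sub-gamma
  (5–20 Hz).
- *1/f exponent*: least-squares slope of log power vs log frequency.
- *Peaked-vs-1/f classification*: a spectrum is "peaked" when some bin in
  3–100 Hz exceeds 5× its local background, estimated as the median power
  of neighbours within ±10 bins excluding a ±2-bin guard.  A local
  background is used deliberately: the spectrum bends in log-log space near
  its low-frequency knee, so extrapolating a global power-law fit under a
  candidate peak is unreliable there.  The rule is an operationalisation of
  the visual distinction between smooth 1/f-like spectra and spectra
  dominated by a particular frequency.
- *Harmonic detection*: bins where the stimulated/spontaneous power ratio
  exceeds a prominence threshold (default 2), is a local maximum, and
  stands above the local median of the ratio — the last condition keeps a
  broadband power increase from registering as a comb.
- *Dominant peak frequency*: argmax bin refined by parabolic interpolation
  of log power, giving sub-bin (≪ 0.98 Hz) resolution; the PSP-time-course
  sweep shifts peaks by less than one bin.
- *CSD*: `-sigma (phi[i+1] - 2 phi[i] + phi[i-1]) / h²` at interior points,
  inputs in mV and mm converted internally to SI (A/m³), `sigma = 0.3 S/m`;
  positive values mark current sources.  Endpoints are dropped for the CSD
  and passed through for the three-point Hamming smoother
  (0.23, 0.54, 0.23).  Point-source CSD maps subtract the mean over the
  analysis window, following standard evoked-CSD practice.

## Calibration

The synaptic gains are the model's free parameters.  The shipped pair
`G_e = 4.8e-5`, `G_i = 1.08e-4` V/spike was chosen, together with the
relative map counts, by a coarse grid search against four requirements,
then frozen: (1) the spontaneous LFP spectrum is 1/f-like (no bin above 5×
its local background); (2) constant visual stimulation raises gamma-band
power; (3) every population stays within 10 mV of rest over a full
schedule; (4) spontaneous oscillation amplitudes fall in the
electrophysiological range, ≈0.1 mV in the thalamically dominated layers
IV and VI and ≈0.05 mV elsewhere, all below 0.2 mV.  At the calibrated
point the margins are comfortable: maximum excursion ≈4–5 mV, amplitudes
≈0.10/0.05 mV, gamma-power ratio ≈40×.

Two further named operating points are fixed in `experiments`:
`PEAKED_GAINS` (5× and 2.5× the calibrated pair), a representative
seizure-like pair whose spontaneous spectrum is dominated by a ≈9 Hz limit
cycle, and `LAYER4_FLIP_CANDIDATES`, gain pairs near the oscillation
boundary searched by the layer-IV-reduction experiment.  In the peaked
regime the stimulated epoch exceeds the 50 mV diagnostic bound; sweeps
record those epochs as failures and classify cells from the spontaneous
epoch, which matches how the regimes are defined.

## The PSP-time-course sweep

The sweep multiplies the excitatory PSP rise and decay constants by a
scale factor.  By default the excitatory gain is divided by the same
factor (`preserve_area=True`), holding the kernel's time integral — net
synaptic charge per spike — constant so that only the kinetics vary.
Without this normalisation, stretching a peak-normalised kernel also
multiplies the total excitatory drive, which conflates a kinetic effect
with a strength effect and destabilises the peaked regime at 2×.  With it,
the dominant-peak frequency shifts monotonically: slower EPSPs lower the
oscillation frequency, faster EPSPs raise it.

## What the synthetic conditions do and do not show

All inputs are synthetic: uniform white noise and deterministic pulse
trains standing in for retinal/LGN drive.  Passing tests demonstrate the
model's internal dynamics — laminar amplitude contrasts, 1/f-like
background, gamma enhancement, SSVEP harmonics, surround inhibition in the
point-source response — under these idealised drives.  They do not show
retinotopic or feature-tuned processing (no patterned stimuli), realistic
low-frequency LFP content (no cortico-cortical feedback loops), or
extracellular filtering (the LFP is an aggregate membrane potential, not a
volume-conducted field).

## Numerical choices and limitations

- Fixed 1 ms step; other steps are rejected because the delay
  discretisation (round, floor 1 step) is tied to it.
- Exact exponential updates for PSP filters and membranes: no step-size
  error in the linear parts; the only discretisation error is the
  zero-order hold on afferent rates.
- Lateral propagation via per-delay-ring kernels and batched real FFTs;
  the rate-field history and its transform live in a ring buffer sized by
  the longest delay.  A straight-loop reference implementation in the test
  suite agrees to ≤1e-9 relative.
- Determinism: a run is a pure function of (config, seed); two runs with
  the same seed are bitwise identical.
- Degenerate inputs: empty bands, too-short profiles, zero neuron counts,
  out-of-grid coordinates and invalid schedules raise `ConfigError`
  rather than returning silent defaults.
- The micrometre "column-scale" variant with global interlaminar coupling,
  multiple excitatory subtypes, and AMPA/NMDA receptor kinetics are out of
  scope.
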