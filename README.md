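# laminarcortex

A laminar continuum (neural mean-field) simulator of cortical local field
potentials, with the measurement stack used in laminar electrophysiology:
LFP aggregation, power spectra and band powers, 1/f-exponent fitting,
steady-state visual evoked potential (SSVEP) harmonic analysis, and
one-dimensional current source density (CSD).

## Who this is for

Local field potentials reflect the joint activity of tens of thousands of
neurons; simulating each cell is neither tractable nor necessary for
questions about laminar population dynamics.  `laminarcortex` is for
computational neuroscientists who want a forward model of visual-cortex
LFPs at the population level: five cortical laminae (I, II/III, IV, V, VI),
each a 2-D continuum sheet of excitatory/inhibitory population pairs,
coupled by a laminar synaptic connection map and driven by thalamic (LGN)
and cortico-cortical afferents.

## The model

Each population follows, per grid element,

- spike generation `Q(V) = Q_max / (1 + exp(-(V - θ)/σ))`,
- spike propagation with conduction delays (`v_h = 0.24 m/s` lateral,
  `v_v = 1.2 v_h` vertical), exponential lateral spread with unit-sum
  weights, and vertical-only interlaminar coupling,
- PSP generation by a causal biexponential kernel whose peak is the
  synaptic gain `G_e` or `G_i` (V/spike) — the model's free parameters,
- membrane aggregation `τ_m dV/dt = V_rest + drive_E − drive_I − V`,

integrated at a fixed 1 ms step.  Simulated protocols: spontaneous
activity, constant visual stimulation, 10 Hz intermittent light (Gaussian
pulse trains), and a transient point source in layer IV.  See
`docs/methods.md` for the full account, including how the default gains
and connection map were calibrated.

## Worked example

```python
import numpy as np
from laminarcortex import (ModelParams, RunConfig, StimulusProtocol,
                           band_power, fit_power_law, power_spectrum)
from laminarcortex.model import run_simulation

cfg = RunConfig(params=ModelParams(grid_n=10),
                protocol=StimulusProtocol(kind="constant_visual"),
                warmup_ms=10_000.0, stim_ms=3_000.0, seed=7)
res = run_simulation(cfg)

element = res.element_potentials()
for li, layer in enumerate(("I", "II/III", "IV", "V", "VI")):
    w = element[res.spont_window(), li]
    print(f"layer {layer:6}  amplitude {(w.max() - w.min()) / 2:.3f} mV")

lfp = res.lfp()
spont = power_spectrum(lfp[res.spont_window()], res.sample_rate)
stim = power_spectrum(lfp[res.stim_window()], res.sample_rate)
print(f"1/f exponent (5-100 Hz): {fit_power_law(spont, 5, 100):.2f}")
print(f"gamma power  spontaneous {band_power(spont, 30, 100):.2e}  "
      f"stimulated {band_power(stim, 30, 100):.2e} mV^2")
```

prints

```
layer I       amplitude 0.051 mV
layer II/III  amplitude 0.050 mV
layer IV      amplitude 0.108 mV
layer V       amplitude 0.055 mV
layer VI      amplitude 0.101 mV
1/f exponent (5-100 Hz): 2.91
gamma power  spontaneous 2.60e-07  stimulated 1.54e-05 mV^2
```

The spontaneous membrane potential oscillates about twice as strongly in
the thalamically dominated layers IV and VI (~0.1 mV) as elsewhere
(~0.05 mV); the spontaneous LFP spectrum falls off as roughly 1/f²–1/f³;
and constant visual stimulation raises gamma-band (30–100 Hz) power by
more than an order of magnitude.

## Command line

```sh
lcm run --config config.yaml --seed 7 --out out/        # one simulation
lcm analyze out/result.h5 --out out/analysis/           # spectra, CSD, γ
lcm sweep --gains-e 4.8e-5,2.4e-4 --gains-i 1.08e-4,2.7e-4 --out sweep/
lcm scenario ssvep --runs 10 --scaled-down --out ssvep/
```

Scenarios: `laminar_profile`, `point_source_csd`, `ssvep`,
`layer4_reduction`; the library module `laminarcortex.experiments` adds
`gain_sweep`, `layer4_flip_search` and `psp_sweep`.

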