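# obhfo

Analysis of respiration-coupled high-frequency oscillations (HFO) in
laminar local field potential (LFP) recordings from the olfactory bulb,
together with a ground-truth forward-model generator so that every stage
of the pipeline can be validated without any experimental data.

Under ketamine–xylazine anesthesia the rodent olfactory bulb produces a
prominent 80–130 Hz rhythm that rides on the respiration-locked delta
(0.3–3 Hz) oscillation: it occurs in ~100 ms bursts gated by the
respiration phase, reverses polarity across the mitral-layer current
dipole, and is driven by local spiking. `obhfo` implements the complete
measurement chain for this phenomenon — burst detection,
respiration/phase coupling statistics, laminar depth profiling, kernel
current-source-density reconstruction, multi-unit analysis, and
condition-contrast statistics — for anyone analysing laminar probe
recordings of respiration-entrained fast rhythms.

## Core statistics

* **Intertrial phase clustering** of burst phases k₁…kₙ:
  ITPC = |n⁻¹ Σᵣ exp(i kᵣ)| ∈ [0, 1].
* **Tort modulation index** for phase–amplitude coupling: phases are
  binned into N equal bins, Pⱼ is the normalised mean amplitude per bin,
  and MI = (log N − H(P)) / log N — the KL divergence of P from uniform,
  normalised to [0, 1]. Comodulograms evaluate MI over a
  (phase frequency × amplitude frequency) grid.
* **Burst detection**: Hilbert envelope of the band-passed signal
  thresholded at mean + 3 SD of a robust (median/MAD) baseline.
* **1D kernel CSD**: sources modelled as Gaussian bases bⱼ(z), mapped to
  electrode potentials by a quasi-1D line-source forward operator;
  estimate Ĉ(z) = K̃(z)·(K + λI)⁻¹·V with λ chosen by
  leave-one-electrode-out cross-validation.
* **Resampling test** for group comodulogram differences: per cell,
  |mean_A − mean_B| against a pooled redraw null (draws with
  replacement), with add-one-smoothed p-values.
* **Normality-gated tests**: Shapiro–Wilk per group, then paired
  t / one-way ANOVA (Gaussian) or Wilcoxon / Friedman + Nemenyi
  (non-Gaussian).

The synthetic generator (`obhfo.synthlfp`) renders all of this with
known ground truth: a jittered respiration phase oscillator, delta and
HFO sources projected through sign-reversing laminar dipole profiles,
von Mises gating of burst times by respiration phase, HFO-phase-locked
spike transients, and 1/f + white noise with a common-mode share.

## Worked example

```python
import numpy as np
from obhfo import ProbeGeometry, GroundTruth, HFO, DELTA
from obhfo.synthlfp import generate_laminar_recording
from obhfo.sigproc import bandpass, analytic_envelope_phase
from obhfo import coupling as cpl

gt = GroundTruth(seed=3, duration=60.0, fs=2000.0, coupling_kappa=8.0)
sim = generate_laminar_recording(gt, ProbeGeometry())   # 32 ch, 100 um

filt = bandpass(sim.lfp, HFO)
env, _ = analytic_envelope_phase(filt.samples[14])      # dorsal dipole lobe
bursts = cpl.detect_bursts(env, gt.fs, band=HFO, channel=14)
delta = bandpass(sim.lfp, DELTA)
ps = cpl.burst_delta_phase(bursts, delta.samples[16], gt.fs)
print(len(bursts), round(cpl.itpc(ps), 3), round(ps.circular_mean(), 3))
```

prints

```
52 0.943 0.717
```

— 52 detected bursts (53 were generated), whose phases relative to the
local delta peak cluster strongly (ITPC 0.943) around 0.717 rad, within
0.07 rad of the configured lock phase π/4 ≈ 0.785: the pipeline recovers
the generator's coupling parameters from the rendered signal alone.

The same flow is available end to end from the shell:

```bash
obhfo run --out runs/demo --seed 1        # simulate -> spectra -> bursts ->
                                          # coupling -> laminar -> stats
obhfo config --dump-defaults              # the embedded demo configuration
```

The run writes recordings (flat float32 + JSON sidecar), burst tables and
comodulograms (CSV), a `report.json` with the recovered parameters, and a
`manifest.json` with the config hash and output checksums.

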