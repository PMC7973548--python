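# Methods

## The signal model

The package analyses a laminar picture of respiration-entrained fast
oscillations: a slow delta (0.3–3 Hz) LFP component that tracks nasal
respiration, and 80–130 Hz oscillations that occur as ~100 ms bursts
preferentially at a particular phase of the respiration/delta cycle.
Both components are generated by laminar current dipoles, so each
reverses polarity at a characteristic depth; the fast rhythm is driven
by local spiking that locks to the trough of its own cycle.

The synthetic generator (`obhfo.synthlfp`) is a forward model of exactly
this structure, with every parameter known:

* **Respiration** is a phase oscillator: successive cycle periods are
  lognormal with mean 1/f_resp and a configurable coefficient of
  variation (default 0.1), and the phase advances linearly within each
  cycle. This gives an exact ground-truth phase reference, which filtered
  noise would not. The rendered trace is −cos θ − 0.15 cos 2θ, so the
  trough (inhalation, by convention) coincides with the LFP delta peak
  (the delta source is cos θ).
* **HFO bursts** are Hann-windowed sinusoids of duration 0.1 s at
  f_hfo = 105 Hz with ±5 Hz per-burst frequency jitter. At most one
  burst is drawn per respiration cycle with probability
  burst_rate/f_resp, and its phase within the cycle is von Mises
  (lock_phase, κ). κ = 0 gives phase-uniform bursts; the defaults are
  lock_phase = π/4 (early descending delta phase) and κ = 4 (κ = 8 in
  the strongly coupled demo configuration).
* **Laminar projection**: each source is multiplied by a depth profile
  w(d) = G(d; c−h, h) − G(d; c+h, h), a difference of Gaussians of
  opposite sign centred ±one halfwidth about the dipole depth c. The
  profile crosses zero exactly at c, giving a clean phase reversal
  without claiming anatomical fidelity. Defaults: HFO dipole at 1600 μm
  (halfwidth 200), delta dipole at 2000 μm (halfwidth 300), on a
  32-channel probe with 100 μm pitch (a 20 μm-pitch dense probe is the
  other standard geometry).
* **Gamma** (50 Hz, spatially uniform, weak) exists so two-condition
  contrasts can scale gamma and HFO power independently
  (amplitudes scale by √scaler, hence band power by the scaler).
* **Spiking**: within each burst, spikes are an inhomogeneous Bernoulli
  process on the sample grid with rate
  mua_rate·|w(d)|·exp(κₘ cos(φ − φ_lock))/I₀(κₘ), where φ is the burst
  carrier phase (peak = 0) and φ_lock = π (trough) by default, κₘ = 4.
  The cycle-averaged rate equals mua_rate·|w(d)| (default 100 Hz at the
  dipole lobe), so expected counts are rate × total burst time. Each
  spike injects a biphasic negative-leading transient (Gaussian widths
  ~0.2 ms, peak 0.15 mV) into the wideband trace.
* **Noise**: white (SD 0.01 mV) plus 1/f-shaped noise (SD 0.02 mV) per
  channel, the 1/f part split 50/50 between an independent and a
  common-mode term, emulating volume-conducted background.

Source amplitudes (delta 0.5, HFO 0.2, gamma 0.05 mV) were chosen once
to give clearly suprathreshold bursts (in-band burst SNR well above 6 dB)
and spike transients whose high-passed peak is ~8× the in-band noise SD —
a typical near-unit extracellular amplitude. The recordings the paper's
in-vivo pipeline faces differ in ways the generator does not attempt to
emulate: non-stationary breathing and arousal state, movement and licking
artifacts, electrode drift, spike waveform diversity, overlapping
oscillators, and line noise. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
every property of real data.

## Analysis conventions

* **Filtering** is zero-phase (forward–backward) Butterworth, order 4
  per pass, so all phase statistics see undistorted timing. The bands
  are delta 0.3–3, gamma 30–65, HFO 80–130, fast HFO 100–180 Hz, and a
  500 Hz high-pass for multi-unit activity (upper edge at Nyquist). A
  settling margin of ~3 impulse-response widths (3/f_lo seconds) is
  excluded from coupling statistics at each end of a filtered trace.
* **Spectra** are Welch estimates: Hann window, 50% overlap, one-sided
  density, 60 s windows by default (shorter with an explicit override).
  Dominant frequency is the within-band argmax; ties break to the lower
  frequency. The band-power timecourse uses sliding windows whose Welch
  segment is a quarter of the window, giving several averages per point.
* **Burst detection** thresholds the Hilbert envelope at
  baseline + 3 SD. The default baseline is robust (median centre,
  1.4826·MAD scale, whole trace) because bursts inflate a plain SD; a
  user-marked quiet segment with plain mean/SD is the alternative.
  Minimum duration is 3 cycles of the band centre and gaps shorter than
  1 cycle are merged — cycle-based defaults motivated by the ~100 ms
  burst scale.
* **Burst phase** is, by default, time-rescaled position between
  successive delta peaks (peak = 0, mapped to (−π, π]), with delta peaks
  found as local maxima separated by at least half the fastest delta
  period; instantaneous Hilbert phase is the alternative mode. Bursts
  outside the first/last delta peak are skipped and counted.
* **Tort MI** uses 18 phase bins and natural logarithms in both the
  entropy and the normalisation (the ratio is base-invariant). Empty
  bins are an error rather than silently merged. Comodulogram cells
  whose phase and amplitude bands overlap are flagged invalid (NaN),
  never computed.
* **Resampling test**: the exchangeable unit is the per-subject cell
  value (resample subjects, not time points). 100,000 draws with
  replacement by default; p-values are add-one smoothed, so the smallest
  attainable p is 1/(n_draws+1). No multiple-comparison correction is
  applied across cells, matching per-cell reporting.
* **Inter-channel phase shift** is the cross-correlation lag (within
  ±half a band-centre cycle) against the reference channel inside each
  burst window, converted to degrees via the band-centre period and
  averaged circularly across bursts. Channels are marked missing when
  silent, when their in-window RMS is below 10% of the reference, when
  their circular resultant across bursts is below 0.6, or when their
  dominant in-band power is below 5% of the strongest channel. The last
  gate matters: common-mode noise gives HFO-silent channels a spuriously
  *consistent* phase, which would otherwise corrupt the reversal-depth
  estimate. The reversal depth is the midpoint of the adjacent channel
  pair with the largest circular phase jump.
* **Kernel CSD (1D)**: Gaussian basis sources (count = 2× channels,
  halfwidth = electrode pitch, grid overshooting the probe by 2 basis
  widths), forward-modelled to potentials with a quasi-1D line-source
  integral assuming a 500 μm source radius (olfactory-bulb layer
  curvature scale). The kernel matrix is normalised to unit mean
  diagonal so the λ grid (10 points, 10⁻⁶…1) is dimensionless; λ is
  selected by leave-one-electrode-out cross-validation of potential
  prediction, deterministically (ties go to the smallest λ). Maps are
  reconstructed first and band-filtered afterwards. The classical
  second-difference CSD is used only as an internal oracle in tests.
  A known property of this estimator family: a depth-uniform potential
  offset is *not* nulled (a smooth source distribution reproduces it,
  and Tikhonov shrinkage retains smooth components preferentially), so
  common-mode rejection must come from the band-pass and from contrasts,
  not from the inversion itself.
* **MUA detection**: 500 Hz high-pass, robust (MAD) noise scale,
  negative-going crossings (extracellular convention; polarity is
  configurable), spike time at the local extremum, 1 ms refractory dead
  time. Detector recall is quoted for temporally isolated spikes
  (nearest neighbour > 2 ms): transients closer than the kernel width
  overlap and cannot be resolved by any threshold detector.
  The burst-aligned spike histogram uses ±100 ms windows and 1 ms bins
  (>9 bins per 105 Hz cycle); its Pearson correlation with the average
  HFO waveform is negative for trough-locked spiking on channels with a
  peak-positive waveform. Note the attainable |r| for a sharply locked
  point process against a sinusoid is well below 1 (a nonnegative comb
  correlates imperfectly with a cosine); ~0.5 is the typical value at
  the default locking sharpness.
* **Gated statistics**: Shapiro–Wilk per group at α = 0.05. Gaussian →
  paired t (two paired groups), repeated-measures one-way ANOVA (≥3
  epochs), or one-way ANOVA (independent). Non-Gaussian → Wilcoxon,
  Friedman + Nemenyi (rank / studentized-range formulation, referred to
  q·√2 with infinite degrees of freedom), or Kruskal–Wallis. A block in
  which every subject is constant across epochs is reported as the
  all-tie case (statistic 0, p 1). Constant groups fail the normality
  gate by definition. No correction across metrics (per-band reporting).

## Problem sizes

The validation suite and the acceptance script use synthetic sessions
sized for precise recovery at desk scale: 300 s single-shank sessions
for coupling recovery (≈300 bursts; lock-phase error ~0.03 rad), 60–120 s
32-channel sessions for laminar analyses, 30 s at 8 kHz for spike-timing
checks, 10,000-draw resampling calibrations, 1000 small-replicate
null datasets for the type-I rate and 100 for power. These sizes are the
package's validation conditions; all estimators accept arbitrarily long
inputs.

## Known limitations

* The generator draws at most one burst per respiration cycle, so burst
  rates above the respiration rate are truncated; burst_rate·f_resp⁻¹ is
  capped at 1 as an occurrence probability.
* The comodulogram uses fixed half-widths (0.5 Hz phase, 15 Hz
  amplitude) rather than scale-adaptive bands; very low phase
  frequencies (< 0.2 Hz) would need wider windows than the defaults.
* kCSD is strictly 1D (depth); it does not model lateral source
  structure, electrode tilt, or conductivity jumps, and its amplitude
  units are arbitrary.
* The gated test chooser applies the Shapiro–Wilk gate at n as small as
  3, where the test has little power; with such groups the parametric
  branch is chosen essentially by default.
* Wilcoxon p-values at n = 8 are discrete (minimum two-sided p
  0.0078), which makes the realised type-I rate slightly conservative
  when the gate routes null data to the nonparametric branch.
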