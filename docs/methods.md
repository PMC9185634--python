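# Methods

This note records the models, parameter choices and numerical decisions
behind `ripfatigue`, and what the synthetic-data experiments do and do not
demonstrate.

## Respiratory synchrony chain

Each trial's chest and abdomen RIP channels pass through:

1. **FIR band-pass 0.15–0.45 Hz.** Linear-phase Kaiser-window design sized
   for ≥ 45 dB stopband attenuation with stopband edges at half the lower
   cutoff and twice the upper cutoff; the symmetric taps are applied by
   reflection-padded convolution, which is zero-phase and cancels a constant
   input exactly (the taps are mean-corrected so the DC gain is identically
   zero). Zero phase matters because the whole method rests on relative
   phase between the two channels.
2. **Downsampling to 40 Hz.** Polyphase FIR resampling (anti-aliased, zero
   phase); rational ratios are supported so the pipeline also accepts
   reduced-rate synthetic inputs.
3. **Masked-sift EMD, first IMF.** Written in-house (no EMD package is a
   dependency): cubic-spline envelopes through extrema with two mirrored
   edge knots per side, sift stopping at a normalised squared-difference of
   0.2 or 10 iterations; a masking sinusoid at the dominant breathing
   frequency (zero-crossing estimate, amplitude 2× the signal SD) is added
   at 4 evenly spaced phases, each masked signal sifted, the mask removed,
   and the results averaged. Masking prevents slow drift from mixing into
   the breathing mode.
4. **z-normalisation**, then phase extraction.

The instantaneous phase is the angle of x + i·H[x]. H is the discrete
Hilbert transform with kernel (2/π)/k over opposite-parity offsets k,
evaluated as an FFT linear convolution; it agrees with the literal O(N²)
double sum to rounding error. Because the sum is truncated at the observed
samples, the transform carries O(1/d) leakage at distance d from the edges
(≈ 8·10⁻³ mid-sequence at N = 256, ≈ 7·10⁻⁵ at N = 24 000); trials are long
enough that this is negligible for the phase.

**Where the 10-s sliding average sits.** A 10-s moving average applied to a
0.25-Hz oscillation multiplies it by |Dirichlet gain| ≈ 0.13 — it would
essentially delete the breathing signal before its phase could be measured,
leaving a noise-dominated residual with an ill-defined phase. The package
therefore computes phase synchrony and the rolling correlation on the
z-normalised first IMF and applies the 10-s sliding average to the
resulting synchrony series; the rolling correlation is already a 10-s
window statistic and is not smoothed twice. `znorm_and_smooth` (z-score
followed by the centred 10-s average) remains available for exported signal
traces. The wrapped reading of the synchrony statistic,
φ = 1 − sin(|wrap(Δ∅)|/2) with Δ∅ ∈ (−π, π], is used throughout: it is the
only reading that keeps φ in [0, 1] with φ = 1 in phase and φ = 0 in
antiphase.

The rolling-correlation window defaults to 10 s (one parameter family with
the smoothing window; configurable). Window positions without a full
window, or with zero variance, are missing and are excluded from decile
means rather than zero-filled.

## EMG features

4th-order Butterworth band-pass 10–500 Hz applied forward–backward; at a
1000-Hz sampling rate the upper cutoff coincides with Nyquist and is
clipped to 0.99·Nyquist (495 Hz), which is logged. Envelope: centred
sliding RMS, 100 ms. The MVC reference is, per bout, the mean of the 100-ms
envelope window centred on the envelope maximum, maximised over the three
bouts. Median frequency: Welch PSD (1-s Hann segments, 50% overlap) on the
band-passed signal (a toggle selects the raw signal), with the median
interpolated linearly *on cumulative power at bin edges* — interpolating at
bin centres biases the estimate low by half a bin (≈ 0.5 Hz at 1-s
segments), which is visible at the ±2 Hz recovery tolerance.

Decile spans partition each trial exactly (boundaries at ⌊i·n/10⌋), so
division means never share samples.

## Accelerometer

Axes: x medio-lateral, y antero-posterior, z superior-inferior. Band-pass
0.1–10 Hz (4th-order Butterworth, zero phase) plus a centred 0.2-s moving
average. Cycle boundaries are the phase-wrap events (+π → −π) of the
z-scored y-axis's analytic phase — one wrap per oscillation, i.e. the
normalised transition maximum of each cycle. Segments shorter than 25% of
the median cycle length are merged into a neighbour (an automatic stand-in
for manual inspection of the segmentation); edge partials count as cycles
when at least half the median length. A segmentation is flagged unreliable
when it finds fewer than 3 cycles or the cycle-duration coefficient of
variation exceeds 0.5 — white noise and static signals fail this test.

Pitch and roll use the arctangent tilt formulas and are reported in
degrees. They are computed on a smoothed-only copy of the trial frame: the
band-pass removes the gravity component that the tilt formulas need, so
angles from fully band-passed axes would be noise ratios. Per trial the
angle series is summarised by its mean absolute deviation (configurable to
SD or range) — a robust oscillation-amplitude proxy; only the ordering
across trials is interpreted.

## Statistical layer

All modelled variables are Yeo-Johnson power-transformed (λ by maximum
likelihood) and z-scored across the pooled sample before fitting, so
coefficients are comparable across metrics. The mixed model has categorical
fixed effects trial (reference Baseline) and division (reference 1), plus
optional covariates, and a per-subject random intercept, fitted by REML
(statsmodels MixedLM, max 200 iterations); non-convergence is flagged on
the result rather than raised. With a singular random-effects covariance
(variance estimated at zero) residuals fall back to marginal residuals
about the fixed-effects fit.

Residual checks: normality by Shapiro–Wilk; homoscedasticity by White's LM
test on the categorical design; independence by a Wald test that the lag-1
autocorrelation of residuals (pairs formed within subject only) is zero —
the specific independence test is a package choice, as "a Wald test" admits
many readings.

Repeated-measures ANOVA uses pingouin with Mauchly's sphericity test and
Greenhouse-Geisser-corrected degrees of freedom and p-value when sphericity
is rejected; partial η² as effect size; pairwise paired t-tests are
Bonferroni-corrected by the number of pairs. Degenerate designs are handled
explicitly: no within-subject variation → F = 0, p = 1; zero residual
variance with real condition differences → F = ∞, p = 0; fewer subjects
than conditions → sphericity not assessable, no correction applied. The
significance level is 5% throughout.

## Synthetic-data generator

The generator emulates the study design — 22 subjects; MVC bouts
(3 × 3.5 s per muscle), a 2-min rest, three 10-min trials with 30-s gaps, a
closing rest; all channels at 1000 Hz — and is a pure function of
(config, seed). Ground truth is written to a separate sidecar and never
into the recording files.

* **Respiration**: a frequency-wandering oscillator (0.25 ± 0.03 Hz between
  subjects, 5% slow within-subject wander) with a 15% second harmonic. The
  abdomen is the same oscillator delayed by the lag profile: per-trial
  means (0.7156, 0.8010, 0.7796) rad — chosen so the synchrony statistic
  sits near 0.65 / 0.61 / 0.62 per trial, the direction and rough size of
  the fatigue effect the method is meant to detect — plus a 0.17-rad
  between-subject offset and 0.13-rad slow within-trial wander, and an
  optional linear drift for trend-recovery scenarios. Noise: a shared
  0.02-Hz baseline drift (posture/motion affects both bands coherently;
  per-compartment log-normal gain), plus independent pink (SD 0.08) and
  white (SD 0.05) sensor noise per channel.
* **EMG**: Gaussian noise shaped to a flat spectral band whose median is
  the target (band starts at 20 Hz so the analysis band-pass leaves the
  median unbiased; sharp FIR edges keep the realised median within a
  fraction of a hertz). Amplitude is calibrated against MVC bouts
  generated as constant-envelope 150-Hz tone bursts, whose plateau RMS the
  MVC reference recovers exactly; the task %MVC and median-frequency
  targets default to the per-trial values of the emulated study (biceps
  16.7/19.0/18.2 %MVC, 62.8/63.3/62.2 Hz; trapezius 12.7/13.5/14.2 %MVC,
  78.5/80.8/79.7 Hz) with 5 %MVC and 8 Hz between-subject offsets. A 30%
  unit-mean cyclic amplitude modulation (phase continuous within a trial)
  adds task structure without moving the trial-mean envelope. The trial
  mean of a rectified envelope carries a ≈ −1% Jensen bias relative to the
  stationary RMS target — well inside the ±1 %MVC recovery band.
* **Accelerometer**: a jittered monotone cycle phase generates the
  antero-posterior oscillation (62/60/58 cycles per trial by default, 10%
  duration jitter, per-subject log-normal count multiplier to emulate
  self-pacing); gravity is rotated by pitch/roll oscillations of
  (10, 14, 15)° and (8, 8.5, 11)°. The roll tilt is in quadrature with the
  dynamic antero-posterior acceleration (0.3 g) so the observed oscillation
  amplitude grows monotonically with the configured roll amplitude.
  White sensor noise, SD 0.02 g.

Between-subject variation enters as log-normal multipliers (scale 0.1) on
amplitudes and counts and normal offsets on targets; these are what the
random intercept of the mixed model absorbs.

**What the synthetic experiments show — and don't.** Parameter recovery on
this generator demonstrates that the pipeline measures what it claims when
its assumptions hold: a quasi-periodic single-mode breathing oscillator, a
stationary-in-band EMG noise process, additive sensor noise, a strictly
periodic task. Real recordings add motion artifact in the breathing band
(arm swings deform the trunk bands), non-stationary EMG with
motion-contaminated low frequencies, electrode and posture drift, and
irregular pacing — none of which the generator emulates. Passing recovery
tests therefore validates the implementation, not the field robustness of
the measurement.

## Problem sizes in the tests and scripts

The default generator configuration is the full design (22 subjects,
600-s trials, 1000 Hz). Replicated experiments use reduced designs as the
package's own desk-scale choices: mixed-model recovery runs 100 replicates
of the 22-subject layout with 300-s trials generated at 200 Hz (the RIP
band lives far below either Nyquist rate, so only decile averaging noise
changes); type-I calibration runs 500 null studies of 12 subjects simulated
directly at the decile-table level, where the mixed model operates; EMG and
accelerometer recovery use single-subject studies of 60–120-s trials at the
full 1000-Hz (EMG) or 100-Hz (accelerometer) rates. The demonstration study
under `analysis/` uses 10 subjects, 200-s trials at 500 Hz.

## Known limitations

* The truncated-sum discrete Hilbert transform has edge leakage; the first
  and last few seconds of a trial carry slightly biased phase. Decile means
  over ≥ 12-s divisions make this negligible.
* The masked sift extracts only the first IMF; recordings whose breathing
  mode is not the fastest in-band component (e.g. strong in-band motion
  artifact) would need a mode-selection step.
* `%MVC` recovery assumes MVC bouts free of artifacts; the reference takes
  a maximum and is not robust to transient spikes.
* The mixed model fits a random intercept only; random slopes over
  divisions are not implemented.
* Roll near ±90° pitch is numerically ill-conditioned (gimbal ambiguity of
  tilt-only orientation); the generator keeps orientations away from that
  regime and real use should too.
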