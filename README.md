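# ripfatigue

Quantifying whole-body fatigue during repetitive work from wearable signals:
thoraco-abdominal (a)synchrony measured by respiratory inductance
plethysmography (RIP), local muscle fatigue measured by surface EMG, and
movement strategy measured by a wrist accelerometer.

During fatiguing repetitive work (here: a box-handling task of three 10-min
trials — Baseline, Fatigue 1, Fatigue 2 — separated by a muscle-fatiguing
protocol), the coordination between chest-wall and abdominal-wall excursions
degrades. This package implements the full measurement chain on synthetic
multi-subject recordings with known ground truth, since no human recordings
are distributed with it.

## The statistics at the core

**Instantaneous phase synchrony.** Both RIP channels are band-pass filtered
to the breathing band (0.15–0.45 Hz), downsampled to 40 Hz, and reduced to
their first intrinsic mode function by masked-sift empirical mode
decomposition. With ∅(n) the instantaneous phase of the analytic signal
x(n) + i·H[x](n) (H the discrete Hilbert transform), the synchrony between
chest and abdomen is

    φ(n) = 1 − sin( |wrap(∅_chest(n) − ∅_abdomen(n))| / 2 ) ∈ [0, 1]

with φ = 1 for in-phase and φ = 0 for antiphase breathing. A rolling-window
Pearson correlation r(n) complements it.

**EMG fatigue features.** Per muscle (dominant-side biceps brachii and upper
trapezius): amplitude as %MVC — the sliding-RMS envelope normalised by the
mean of the 100-ms window around the maximal-voluntary-contraction envelope
peak — and the median frequency of the Welch power spectral density.
Fatigue raises %MVC and lowers the median frequency.

**Kinematics.** Wrist task cycles are segmented from the antero-posterior
accelerometer axis via analytic-phase wrap events; orientation is summarised
by pitch = atan(−Acc_x/√(Acc_y²+Acc_z²)) and roll = atan(Acc_y/Acc_z).

**Statistics.** Every metric is aggregated per trial decile (~1 min each),
Yeo-Johnson transformed and z-scored, and modelled with linear mixed-effects
regressions (random intercept per subject; fixed effects trial + division,
optionally EMG covariates). Accelerometer summaries use repeated-measures
ANOVA with Mauchly/Greenhouse-Geisser handling and Bonferroni pairwise
t-tests.

## Worked example

The numbered scripts under `analysis/` run a reduced demonstration study
(10 subjects, 200-s trials at 500 Hz; the generator's defaults are the
full-scale design of 22 subjects and 600-s trials at 1000 Hz):

```sh
python analysis/01_simulate.py     # synthetic study -> scratch/demo_study
python analysis/02_process.py      # signal pipelines -> decile + trial tables
python analysis/03_analyze.py      # mixed models, diagnostics, RM-ANOVA
python analysis/04_report.py       # decile-profile figures (advisory)
```

`02_process.py` prints the per-trial means of the decile metrics:

```
trial            Baseline  Fatigue 1  Fatigue 2
metric
emg_amp_biceps     20.563     22.838     22.044
emg_amp_trap       14.758     15.561     16.243
emg_mf_biceps      63.273     63.931     62.789
emg_mf_trap        79.644     81.999     80.614
rip_correlation     0.787      0.737      0.763
rip_synchrony       0.687      0.648      0.668
```

Synchrony and correlation drop from Baseline to the Fatigue trials while
EMG amplitude rises — the imposed fatigue signature. `03_analyze.py` then
fits the mixed models; on the same run the Fatigue-trial coefficients for
the respiratory metrics are all negative and significant, e.g.

```
      dependent       approach             term   beta      z     p
rip_correlation trial+division trial[Fatigue 1] -0.443 -4.624 0.000
rip_correlation trial+division trial[Fatigue 2] -0.229 -2.395 0.017
  rip_synchrony trial+division trial[Fatigue 1] -0.459 -4.730 0.000
  rip_synchrony trial+division trial[Fatigue 2] -0.215 -2.222 0.026
```

β is on the pooled z-scored scale: Fatigue-1 synchrony sits about 0.46
within-study standard deviations below Baseline after accounting for the
subject random intercept. Tables land in `results/`.

The same pipeline is scriptable through the `ripfatigue` CLI
(`simulate`, `process`, `analyze`, `report`), with every stage parameter
overridable from a YAML config.

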