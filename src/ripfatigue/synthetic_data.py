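"""Multi-subject synthetic recordings with known ground truth.

The generator emulates the study design the pipeline expects: 22 subjects,
three 10-min trials (Baseline, Fatigue 1, Fatigue 2) book-ended by 2-min
rests, MVC bouts at the start of the recording, all channels at 1000 Hz.

What each modality emulates:

* **Respiration (RIP)** — a frequency-wandering breathing oscillator near
  0.25 Hz with a second harmonic, pink baseline drift and white sensor
  noise.  The abdomen channel is the same oscillator delayed by a
  configurable phase lag; the per-trial lag means default to values whose
  synchrony endpoints mirror the drop seen from baseline to fatigued work
  (phase synchrony about 0.65 falling to about 0.61).
* **EMG** — band-limited Gaussian noise whose flat spectral band is centred
  on the target median frequency, amplitude-calibrated against generated
  MVC bouts so the task runs at the configured %MVC; optional within-trial
  amplitude/median-frequency ramps.  MVC bouts are constant-envelope 150-Hz
  tone bursts, so the MVC reference equals the configured bout RMS exactly.
* **Accelerometer** — a known number of jittered task cycles on the
  antero-posterior axis plus gravity components oscillating with the
  configured pitch/roll amplitudes.

Between-subject variation enters as log-normal amplitude multipliers and
normal offsets on the targets.  All outputs are pure functions of
(config, seed); the emitted recording files never contain the truth, which
lives in a separate ground-truth sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d

from .signal_model import Annotation, Recording, TimeSeriesChannel, decile_spans, write_recording

__all__ = ["StudyConfig", "gen_respiration", "gen_emg", "gen_accel",
           "gen_recording", "gen_study"]

TRIALS = ("Baseline", "Fatigue 1", "Fatigue 2")


@dataclass
class MuscleTargets:
    amp_pct_mvc: tuple[float, float, float]
    mf_hz: tuple[float, float, float]
    #: multiplicative amplitude ramp across each trial (start -> end)
    amp_ramp: tuple[float, float] = (1.0, 1.0)
    #: additive median-frequency ramp across each trial, Hz (start -> end)
    mf_ramp_hz: tuple[float, float] = (0.0, 0.0)


@dataclass
class StudyConfig:
    """Study-design parameters; defaults reproduce the emulated protocol."""

    n_subjects: int = 22
    sampling_rate_hz: float = 1000.0
    trial_length_s: float = 600.0
    rest_length_s: float = 120.0
    inter_trial_gap_s: float = 30.0
    modalities: tuple[str, ...] = ("rip", "emg", "accel")

    # --- respiration ---
    breathing_hz_mean: float = 0.25
    breathing_hz_sd: float = 0.03          # between-subject
    breathing_fm: float = 0.05             # fractional slow frequency wander
    #: per-trial mean chest-abdomen phase lag (rad); defaults chosen so the
    #: phase-synchrony statistic sits near 0.65 / 0.61 / 0.62 per trial
    phase_lag_rad: tuple[float, float, float] = (0.7156, 0.8010, 0.7796)
    #: additive within-trial lag drift start -> end (rad)
    phase_lag_drift_rad: tuple[float, float] = (0.0, 0.0)
    phase_lag_between_sd: float = 0.17     # rad, subject offsets
    phase_lag_within_sd: float = 0.13      # rad, slow wander inside a trial
    rip_harmonic: float = 0.15
    rip_pink_sd: float = 0.08
    rip_drift_amp: float = 0.15            # 0.02 Hz baseline drift amplitude
    rip_white_sd: float = 0.05

    # --- EMG ---
    emg: dict[str, MuscleTargets] = field(default_factory=lambda: {
        "biceps": MuscleTargets(amp_pct_mvc=(16.7, 19.0, 18.2),
                                mf_hz=(62.8, 63.3, 62.2)),
        "trapezius": MuscleTargets(amp_pct_mvc=(12.7, 13.5, 14.2),
                                   mf_hz=(78.5, 80.8, 79.7)),
    })
    emg_amp_between_sd: float = 5.0        # %MVC, subject offsets
    emg_mf_between_sd: float = 8.0         # Hz, subject offsets
    emg_cycle_mod_depth: float = 0.3       # per-cycle amplitude modulation
    mvc_bout_s: float = 3.5
    mvc_gap_s: float = 2.0
    n_mvc_bouts: int = 3
    mvc_rms: float = 1.0                   # bout RMS in raw amplitude units

    # --- accelerometer ---
    cycles_per_trial: tuple[int, int, int] = (62, 60, 58)
    cycle_jitter: float = 0.10             # fractional duration jitter
    pitch_amp_deg: tuple[float, float, float] = (10.0, 14.0, 15.0)
    roll_amp_deg: tuple[float, float, float] = (8.0, 8.5, 11.0)
    accel_task_amp_g: float = 0.3          # dynamic antero-posterior amplitude
    accel_noise_sd: float = 0.02           # in g

    # --- between-subject scale ---
    between_subject_sd: float = 0.10       # log-normal amplitude multipliers
    seed: int = 0

    def validate(self) -> None:
        for name in ("breathing_hz_sd", "phase_lag_between_sd", "phase_lag_within_sd",
                     "emg_amp_between_sd", "emg_mf_between_sd", "accel_noise_sd",
                     "between_subject_sd", "cycle_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for m, t in self.emg.items():
            if len(t.amp_pct_mvc) != 3 or len(t.mf_hz) != 3:
                raise ValueError(f"muscle {m!r}: targets needed for all 3 trials")


# ---------------------------------------------------------------------------
# noise helpers

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _slow_noise(n: int, rate: float, rng: np.random.Generator,
                timescale_s: float = 20.0) -> np.ndarray:
    """Unit-SD smooth random wander with the given correlation timescale.

    White noise on a coarse grid (half the timescale), lightly smoothed and
    linearly interpolated to the sample grid — O(n) regardless of timescale.
    """
    step = max(int(timescale_s * rate / 2.0), 1)
    m = n // step + 3
    coarse = uniform_filter1d(rng.standard_normal(m), size=3, mode="nearest")
    x = np.interp(np.arange(n, dtype=float), np.arange(m) * float(step), coarse)
    sd = x.std()
    return x / sd if sd > 0 else x


# ---------------------------------------------------------------------------
# timeline

@dataclass
class _Timeline:
    annotations: list[Annotation]
    duration_s: float

    def trials(self) -> list[Annotation]:
        return [a for a in self.annotations if a.kind == "trial"]


def _build_timeline(cfg: StudyConfig) -> _Timeline:
    anns: list[Annotation] = []
    t = 0.0
    if "emg" in cfg.modalities:
        for muscle in cfg.emg:
            for _ in range(cfg.n_mvc_bouts):
                anns.append(Annotation("mvc", muscle, t, t + cfg.mvc_bout_s))
                t += cfg.mvc_bout_s + cfg.mvc_gap_s
    anns.append(Annotation("rest", "rest_pre", t, t + cfg.rest_length_s))
    t += cfg.rest_length_s
    for i, name in enumerate(TRIALS):
        anns.append(Annotation("trial", name, t, t + cfg.trial_length_s))
        t += cfg.trial_length_s
        if i < 2:
            t += cfg.inter_trial_gap_s
    anns.append(Annotation("rest", "rest_post", t, t + cfg.rest_length_s))
    t += cfg.rest_length_s
    return _Timeline(anns, t)


def _sample_span(ann: Annotation, rate: float) -> tuple[int, int]:
    return (int(np.floor(round(ann.start_s * rate, 9))),
            int(np.floor(round(ann.end_s * rate, 9))))


# ---------------------------------------------------------------------------
# respiration

def gen_respiration(cfg: StudyConfig, timeline: _Timeline, subj: dict,
                    rng: np.random.Generator):
    """Chest/abdomen RIP arrays over the whole timeline, plus per-trial lag truth."""
    rate = cfg.sampling_rate_hz
    n = int(round(timeline.duration_s * rate))
    f0 = subj["breathing_hz"]
    inst_f = f0 * (1.0 + cfg.breathing_fm * _slow_noise(n, rate, rng, 30.0))
    theta = 2 * np.pi * np.cumsum(inst_f) / rate

    # lag profile: per-trial mean + optional linear drift + slow wander,
    # baseline lag elsewhere; lightly smoothed to avoid step transients
    lag = np.full(n, cfg.phase_lag_rad[0] + subj["lag_offset"])
    for i, ann in enumerate(timeline.trials()):
        lo, hi = _sample_span(ann, rate)
        drift = np.linspace(cfg.phase_lag_drift_rad[0], cfg.phase_lag_drift_rad[1], hi - lo)
        lag[lo:hi] = cfg.phase_lag_rad[i] + subj["lag_offset"] + drift
    win = max(int(4.0 * rate), 1)
    lag = uniform_filter1d(uniform_filter1d(lag, win, mode="nearest"), win, mode="nearest")
    lag += cfg.phase_lag_within_sd * _slow_noise(n, rate, rng, 25.0)

    # baseline drift is posture/motion-driven and therefore shared by the two
    # compartments (per-compartment gain only); sensor noise is independent
    t_s = np.arange(n) / rate
    shared_drift = cfg.rip_drift_amp * np.sin(2 * np.pi * 0.02 * t_s + rng.uniform(0, 2 * np.pi))

    def compartment(phase: np.ndarray, amp: float) -> np.ndarray:
        return (amp * (np.sin(phase) + cfg.rip_harmonic * np.sin(2 * phase))
                + np.exp(rng.normal(0.0, 0.2)) * shared_drift
                + cfg.rip_pink_sd * _pink_noise(n, rng)
                + cfg.rip_white_sd * rng.standard_normal(n))

    chest = compartment(theta, subj["amp_mult"])
    abdomen = compartment(theta - lag, subj["amp_mult"] * subj["abd_rel_amp"])

    truth = {}
    for i, ann in enumerate(timeline.trials()):
        lo, hi = _sample_span(ann, rate)
        trial_lag = lag[lo:hi]
        decile_means = [float(np.mean(trial_lag[a:b]))
                        for a, b in decile_spans(ann.duration_s, rate)]
        truth[ann.name] = {
            "lag_mean_rad": float(np.mean(trial_lag)),
            "lag_decile_means_rad": decile_means,
            "phi_expected": [float(1 - np.sin(abs(m) / 2)) for m in decile_means],
        }
    return chest, abdomen, truth


# ---------------------------------------------------------------------------
# EMG

def _shaped_emg_noise(n: int, rate: float, mf_hz: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise with a flat spectral band whose median is ``mf_hz``.

    The band starts at 20 Hz, above the analysis band-pass edge, so the
    pipeline's 10-Hz high-pass leaves the realised spectrum symmetric about
    the target median.
    """
    from scipy.signal import fftconvolve, firwin
    low = 20.0
    high = max(2 * mf_hz - low, low + 10.0)
    high = min(high, 0.49 * rate)
    # sharp transitions (~2 Hz at 1000 Hz) keep the realised spectral median
    # within a fraction of a hertz of the nominal target
    ntaps = min(int(1.6 * rate) | 1, max(n // 4 | 1, 65))
    taps = firwin(ntaps, [low, high], pass_zero=False, fs=rate)
    pad = ntaps
    x = fftconvolve(rng.standard_normal(n + 2 * pad), taps, mode="same")[pad:pad + n]
    return x / x.std()


def gen_emg(cfg: StudyConfig, timeline: _Timeline, muscle: str, subj: dict,
            rng: np.random.Generator):
    """One muscle's EMG over the whole timeline plus realized per-trial targets.

    MVC bouts are 150-Hz tone bursts with a Tukey on/off ramp whose plateau
    RMS equals the subject's MVC scale, so the pipeline's reference recovers
    it exactly; task segments are shaped noise at the realized %MVC target.
    """
    rate = cfg.sampling_rate_hz
    n = int(round(timeline.duration_s * rate))
    targets = cfg.emg[muscle]
    mvc_rms = cfg.mvc_rms * subj["amp_mult"]
    x = 0.002 * mvc_rms * rng.standard_normal(n)  # resting baseline

    from scipy.signal.windows import tukey
    for ann in timeline.annotations:
        if ann.kind == "mvc" and ann.name == muscle:
            lo, hi = _sample_span(ann, rate)
            t = np.arange(hi - lo) / rate
            burst = np.sqrt(2.0) * mvc_rms * np.sin(2 * np.pi * 150.0 * t)
            x[lo:hi] += burst * tukey(hi - lo, 0.4)

    amp_offset = subj["emg_amp_offset"][muscle]     # %MVC
    mf_offset = subj["emg_mf_offset"][muscle]       # Hz
    truth = {}
    for i, ann in enumerate(timeline.trials()):
        lo, hi = _sample_span(ann, rate)
        amp_target = max(targets.amp_pct_mvc[i] + amp_offset, 1.0)
        mf_target = float(np.clip(targets.mf_hz[i] + mf_offset, 30.0, 0.45 * rate))
        # within-trial ramps realised decile block by decile block; the
        # cycle modulation runs continuously over the trial so block means
        # stay on target
        mod_phase = rng.uniform(0, 2 * np.pi)
        spans = decile_spans(ann.duration_s, rate)
        for d, (a, b) in enumerate(spans):
            frac = (d + 0.5) / len(spans)
            amp_mult = targets.amp_ramp[0] + frac * (targets.amp_ramp[1] - targets.amp_ramp[0])
            mf_d = mf_target + targets.mf_ramp_hz[0] + frac * (
                targets.mf_ramp_hz[1] - targets.mf_ramp_hz[0])
            sd = (amp_target * amp_mult / 100.0) * mvc_rms
            seg = sd * _shaped_emg_noise(b - a, rate, mf_d, rng)
            if cfg.emg_cycle_mod_depth > 0:
                t = np.arange(a, b) / rate
                d_mod = cfg.emg_cycle_mod_depth
                # unit-mean modulation: the trial-mean RMS envelope stays on target
                mod = 1.0 + d_mod * np.sin(2 * np.pi * 0.1 * t + mod_phase)
                seg *= mod
            x[lo + a:lo + b] = seg
        mean_ramp = 0.5 * (targets.amp_ramp[0] + targets.amp_ramp[1])
        truth[ann.name] = {
            "amp_pct_mvc": amp_target * mean_ramp,
            "mf_hz": mf_target + 0.5 * (targets.mf_ramp_hz[0] + targets.mf_ramp_hz[1]),
        }
    return x, truth


# ---------------------------------------------------------------------------
# accelerometer

def _cycle_phase(n_cycles: int, n_samples: int, jitter: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Monotone phase 0 -> 2*pi*n_cycles over the span, jittered cycle lengths."""
    durations = 1.0 + jitter * rng.uniform(-1, 1, size=n_cycles)
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    edges *= n_samples / edges[-1]
    phase = np.interp(np.arange(n_samples), edges, 2 * np.pi * np.arange(n_cycles + 1))
    return phase


def gen_accel(cfg: StudyConfig, timeline: _Timeline, subj: dict,
              rng: np.random.Generator):
    """Triaxial wrist acceleration over the timeline plus per-trial truth."""
    rate = cfg.sampling_rate_hz
    n = int(round(timeline.duration_s * rate))
    g = 1.0
    pitch_rad = np.zeros(n)
    roll_rad = np.zeros(n)
    dyn_y = np.zeros(n)
    truth = {}
    for i, ann in enumerate(timeline.trials()):
        lo, hi = _sample_span(ann, rate)
        k = max(3, int(round(cfg.cycles_per_trial[i] * subj["cycle_mult"])))
        theta = _cycle_phase(k, hi - lo, cfg.cycle_jitter, rng)
        p_amp = np.radians(cfg.pitch_amp_deg[i]) * subj["angle_mult"]
        r_amp = np.radians(cfg.roll_amp_deg[i]) * subj["angle_mult"]
        # roll tilt in quadrature with the dynamic y-acceleration, so the
        # combined antero-posterior oscillation grows monotonically with the
        # configured roll amplitude
        pitch_rad[lo:hi] = p_amp * np.sin(theta + np.pi / 4)
        roll_rad[lo:hi] = r_amp * np.sin(theta)
        dyn_y[lo:hi] = -cfg.accel_task_amp_g * np.cos(theta)
        truth[ann.name] = {
            "n_cycles": int(k),
            "pitch_amp_deg": float(np.degrees(p_amp)),
            "roll_amp_deg": float(np.degrees(r_amp)),
        }
    acc_x = -g * np.sin(pitch_rad)
    acc_y = g * np.cos(pitch_rad) * np.sin(roll_rad) + dyn_y
    acc_z = g * np.cos(pitch_rad) * np.cos(roll_rad)
    noise = cfg.accel_noise_sd
    return (acc_x + noise * rng.standard_normal(n),
            acc_y + noise * rng.standard_normal(n),
            acc_z + noise * rng.standard_normal(n),
            truth)


# ---------------------------------------------------------------------------
# assembly

def _subject_params(cfg: StudyConfig, rng: np.random.Generator) -> dict:
    return {
        "breathing_hz": float(np.clip(
            rng.normal(cfg.breathing_hz_mean, cfg.breathing_hz_sd), 0.17, 0.42)),
        "lag_offset": float(rng.normal(0.0, cfg.phase_lag_between_sd)),
        "amp_mult": float(np.exp(rng.normal(0.0, cfg.between_subject_sd))),
        "abd_rel_amp": float(np.exp(rng.normal(0.0, 0.5 * cfg.between_subject_sd))),
        "angle_mult": float(np.exp(rng.normal(0.0, cfg.between_subject_sd))),
        # self-paced cycle counts differ between subjects
        "cycle_mult": float(np.exp(rng.normal(0.0, cfg.between_subject_sd))),
        "emg_amp_offset": {m: float(rng.normal(0.0, cfg.emg_amp_between_sd))
                           for m in cfg.emg},
        "emg_mf_offset": {m: float(rng.normal(0.0, cfg.emg_mf_between_sd))
                          for m in cfg.emg},
    }


def gen_recording(cfg: StudyConfig, subject_idx: int,
                  rng: np.random.Generator) -> tuple[Recording, dict]:
    """Generate one subject's Recording and its ground-truth dict (in memory)."""
    cfg.validate()
    timeline = _build_timeline(cfg)
    subj = _subject_params(cfg, rng)
    subject_id = f"S{subject_idx + 1:02d}"
    channels: dict[str, TimeSeriesChannel] = {}
    truth: dict = {"subject_id": subject_id, "params": subj, "trials": {t: {} for t in TRIALS}}

    if "rip" in cfg.modalities:
        chest, abdomen, rip_truth = gen_respiration(cfg, timeline, subj, rng)
        channels["rip_chest"] = TimeSeriesChannel("rip_chest", chest, cfg.sampling_rate_hz, "a.u.")
        channels["rip_abdomen"] = TimeSeriesChannel("rip_abdomen", abdomen, cfg.sampling_rate_hz, "a.u.")
        for t, d in rip_truth.items():
            truth["trials"][t]["rip"] = d
    if "emg" in cfg.modalities:
        for muscle in cfg.emg:
            x, emg_truth = gen_emg(cfg, timeline, muscle, subj, rng)
            channels[f"emg_{muscle}"] = TimeSeriesChannel(
                f"emg_{muscle}", x, cfg.sampling_rate_hz, "a.u.")
            for t, d in emg_truth.items():
                truth["trials"][t].setdefault("emg", {})[muscle] = d
    if "accel" in cfg.modalities:
        ax, ay, az, acc_truth = gen_accel(cfg, timeline, subj, rng)
        for lab, arr in (("acc_x", ax), ("acc_y", ay), ("acc_z", az)):
            channels[lab] = TimeSeriesChannel(lab, arr, cfg.sampling_rate_hz, "g")
        for t, d in acc_truth.items():
            truth["trials"][t]["accel"] = d

    rec = Recording(subject_id=subject_id, channels=channels,
                    annotations=list(timeline.annotations),
                    metadata={"synthetic": True, "subject_index": subject_idx})
    return rec, truth


def gen_study(cfg: StudyConfig, out_dir) -> list[Path]:
    """Write a full synthetic study: recordings, ground-truth sidecars, manifest."""
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    paths = []
    for i in range(cfg.n_subjects):
        rec, truth = gen_recording(cfg, i, np.random.default_rng(seeds[i]))
        path = write_recording(rec, out_dir / f"{rec.subject_id}.csv")
        (out_dir / f"{rec.subject_id}.truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True))
        paths.append(path)
    manifest = {"config": _cfg_to_dict(cfg), "n_subjects": cfg.n_subjects, "seed": cfg.seed}
    (out_dir / "study_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return paths


def _cfg_to_dict(cfg: StudyConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d
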