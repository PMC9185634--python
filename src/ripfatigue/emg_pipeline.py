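"""Surface-EMG fatigue features: %MVC amplitude and Welch median frequency.

Raw EMG is band-pass filtered (4th-order Butterworth, 10-500 Hz, the upper
edge clipped just below Nyquist when the sampling rate makes 500 Hz
unrealisable), rectified into a sliding-RMS envelope, and expressed as a
percentage of a maximal-voluntary-contraction (MVC) reference: the mean of
the 100-ms envelope window centred on the envelope maximum, maximised over
the recorded MVC bouts.

Myoelectric fatigue raises the task amplitude (%MVC) and shifts the power
spectrum downward; the spectral marker is the median frequency of the Welch
power spectral density, interpolated within the crossing bin.  Both features
are summarised per trial decile (ten contiguous divisions, about one minute
each for a 10-min trial).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .signal_model import (
    Recording,
    TimeSeriesChannel,
    ValidationError,
    decile_spans,
    slice_annotation,
)

__all__ = [
    "EMGParams",
    "MVCReference",
    "EMGFeatures",
    "butter_bandpass",
    "rms_envelope",
    "mvc_reference",
    "normalize_to_mvc",
    "median_frequency",
    "emg_features_by_decile",
]

log = logging.getLogger(__name__)

#: muscles analysed (dominant limb); other channels are carried but unused
ANALYZED_MUSCLES = ("biceps", "trapezius")


@dataclass
class EMGParams:
    band_hz: tuple[float, float] = (10.0, 500.0)
    order: int = 4
    rms_ms: float = 100.0
    welch_win_s: float = 1.0
    welch_overlap: float = 0.5
    #: median frequency computed on the band-passed signal (toggle to use raw)
    mf_on_filtered: bool = True


@dataclass
class MVCReference:
    """Per-muscle maximal-contraction amplitude reference."""

    muscle: str
    reference_value: float
    trial_peaks: list[float]

    def __post_init__(self) -> None:
        if not (self.reference_value > 0):
            raise ValidationError(f"MVC reference for {self.muscle!r} must be positive")


@dataclass
class EMGFeatures:
    muscle: str
    trial: str
    division: int
    amplitude_pct_mvc: float
    median_freq_hz: float


def butter_bandpass(x: TimeSeriesChannel, low_hz: float = 10.0,
                    high_hz: float = 500.0, order: int = 4) -> TimeSeriesChannel:
    """Zero-phase Butterworth band-pass; the high edge is clipped below Nyquist."""
    if low_hz >= high_hz:
        raise ValidationError(f"invalid band [{low_hz}, {high_hz}]")
    nyq = x.sampling_rate / 2.0
    if high_hz >= nyq:
        clipped = 0.99 * nyq
        log.info("EMG high cutoff %.1f Hz unrealisable at %.0f Hz sampling; clipped to %.1f Hz",
                 high_hz, x.sampling_rate, clipped)
        high_hz = clipped
    if low_hz >= high_hz:
        raise ValidationError("band collapsed after Nyquist clipping")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=x.sampling_rate, output="sos")
    return x.replace(samples=sps.sosfiltfilt(sos, x.samples))


def rms_envelope(x: TimeSeriesChannel, window_ms: float = 100.0) -> TimeSeriesChannel:
    """Centred sliding root-mean-square envelope, length preserved."""
    win = int(round(window_ms * 1e-3 * x.sampling_rate))
    if win < 2:
        raise ValidationError("RMS window must span at least 2 samples")
    ms = uniform_filter1d(x.samples ** 2, size=win, mode="nearest")
    return x.replace(samples=np.sqrt(np.maximum(ms, 0.0)))


def mvc_reference(mvc_segments: list[TimeSeriesChannel], window_ms: float = 100.0,
                  muscle: str = "") -> MVCReference:
    """MVC amplitude reference from one or more maximal-contraction bouts.

    Per bout: smooth with the sliding RMS, find the envelope maximum, and
    average the 100-ms window centred on it.  The reference is the maximum of
    these per-bout values.
    """
    if not mvc_segments:
        raise ValidationError("at least one MVC segment is required")
    peaks: list[float] = []
    for seg in mvc_segments:
        env = rms_envelope(seg, window_ms).samples
        win = int(round(window_ms * 1e-3 * seg.sampling_rate))
        i = int(np.argmax(env))
        lo = max(0, i - win // 2)
        hi = min(env.size, lo + win)
        peaks.append(float(np.mean(env[lo:hi])))
    return MVCReference(muscle=muscle, reference_value=max(peaks), trial_peaks=peaks)


def normalize_to_mvc(envelope: TimeSeriesChannel, ref: MVCReference) -> TimeSeriesChannel:
    """Express an RMS envelope as percent of the MVC reference."""
    if ref.reference_value <= 0:
        raise ValidationError("MVC reference must be positive")
    out = envelope.replace(samples=100.0 * envelope.samples / ref.reference_value)
    out.unit = "%MVC"
    return out


def median_frequency(x: TimeSeriesChannel, welch_win_s: float = 1.0,
                     welch_overlap: float = 0.5) -> float:
    """Median of the Welch power spectral density (Hz), interpolated in the crossing bin."""
    nperseg = int(round(welch_win_s * x.sampling_rate))
    if x.samples.size < 2 * nperseg:
        raise ValidationError("segment must span at least two Welch windows")
    f, pxx = sps.welch(x.samples, fs=x.sampling_rate, window="hann",
                       nperseg=nperseg, noverlap=int(round(welch_overlap * nperseg)))
    total = float(np.sum(pxx))
    if total <= 0:
        raise ValidationError("zero-power segment has no median frequency")
    cum = np.cumsum(pxx)
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    # the cumulative reaches cum[i] at the *upper edge* of bin i; interpolate
    # on bin edges, else the estimate is biased low by half a bin
    df = f[1] - f[0]
    prev = cum[i - 1] if i > 0 else 0.0
    frac = (half - prev) / (cum[i] - prev)
    return float(f[i] - df / 2.0 + frac * df)


def mvc_reference_from_recording(rec: Recording, muscle: str,
                                 params: EMGParams | None = None) -> MVCReference:
    """Build the MVC reference from a recording's annotated MVC bouts."""
    params = params or EMGParams()
    anns = rec.mvc_annotations(muscle)
    if not anns:
        raise ValidationError(f"subject {rec.subject_id!r}: no MVC annotations for {muscle!r}")
    channel = rec.channels[f"emg_{muscle}"]
    segments = []
    for ann in anns:
        seg = slice_annotation(rec, ann).channels[f"emg_{muscle}"]
        segments.append(butter_bandpass(seg, *params.band_hz, order=params.order))
    return mvc_reference(segments, params.rms_ms, muscle=muscle)


def emg_features_by_decile(rec: Recording, muscle: str, ref: MVCReference,
                           params: EMGParams | None = None) -> list[EMGFeatures]:
    """Per-trial, per-decile mean %MVC and median frequency for one muscle."""
    params = params or EMGParams()
    label = f"emg_{muscle}"
    if label not in rec.channels:
        raise ValidationError(f"subject {rec.subject_id!r} lacks channel {label!r}")
    trials = rec.trial_annotations()
    if not trials:
        raise ValidationError(f"subject {rec.subject_id!r} has no trial annotations")
    out: list[EMGFeatures] = []
    for ann in sorted(trials, key=lambda t: t.start_s):
        raw = slice_annotation(rec, ann).channels[label]
        filtered = butter_bandpass(raw, *params.band_hz, order=params.order)
        env = normalize_to_mvc(rms_envelope(filtered, params.rms_ms), ref)
        spectral_src = filtered if params.mf_on_filtered else raw
        for div, (lo, hi) in enumerate(
                decile_spans(ann.duration_s, raw.sampling_rate), start=1):
            amp = float(np.mean(env.samples[lo:hi]))
            mf = median_frequency(
                spectral_src.replace(samples=spectral_src.samples[lo:hi]),
                params.welch_win_s, params.welch_overlap)
            out.append(EMGFeatures(muscle=muscle, trial=ann.name, division=div,
                                   amplitude_pct_mvc=amp, median_freq_hz=mf))
    return out


def emg_decile_records(rec: Recording, params: EMGParams | None = None):
    """DecileTable records for all analysed muscles of one recording."""
    short = {"biceps": "biceps", "trapezius": "trap"}
    records = []
    for muscle in ANALYZED_MUSCLES:
        ref = mvc_reference_from_recording(rec, muscle, params)
        for feat in emg_features_by_decile(rec, muscle, ref, params):
            records.append({"subject_id": rec.subject_id, "trial": feat.trial,
                            "division": feat.division,
                            "metric": f"emg_amp_{short[muscle]}",
                            "value": feat.amplitude_pct_mvc})
            records.append({"subject_id": rec.subject_id, "trial": feat.trial,
                            "division": feat.division,
                            "metric": f"emg_mf_{short[muscle]}",
                            "value": feat.median_freq_hz})
    return records
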