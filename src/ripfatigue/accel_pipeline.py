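"""Wrist-accelerometer kinematics: task-cycle segmentation and pitch/roll.

Axes follow the box-handling task convention: x = medio-lateral,
y = antero-posterior, z = superior-inferior.  Each axis is band-passed
(4th-order Butterworth, 0.1-10 Hz, zero phase) and smoothed with a centred
0.2-s moving average.  Task cycles are segmented on the antero-posterior
axis: the z-scored signal's analytic phase is computed and each wrap of the
normalised phase (+pi -> -pi transition, i.e. the transition maximum of the
oscillation) marks a cycle boundary; implausibly short segments (< 25% of
the median cycle length) are merged into a neighbour, standing in for the
manual inspection an operator would otherwise perform.

Orientation angles come from the arctangent tilt formulas

    pitch = atan(-acc_x / sqrt(acc_y^2 + acc_z^2))      (degrees)
    roll  = atan(acc_y / acc_z)                          (degrees)

and are summarised per trial by the mean absolute deviation of the angle
series (a robust oscillation-amplitude proxy; SD and range are available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .rip_pipeline import discrete_hilbert
from .signal_model import Annotation, TimeSeriesChannel, ValidationError

__all__ = [
    "AccelParams",
    "AccelFrame",
    "CycleSegmentation",
    "accel_preprocess",
    "segment_cycles",
    "pitch",
    "roll",
    "angle_summary",
    "accel_trial_summary",
]

log = logging.getLogger(__name__)


@dataclass
class AccelParams:
    band_hz: tuple[float, float] = (0.1, 10.0)
    order: int = 4
    smooth_s: float = 0.2
    min_cycle_frac: float = 0.25   # plausibility filter for short segments
    angle_summary: str = "mad"     # "mad" | "sd" | "range"


@dataclass
class AccelFrame:
    """Triaxial acceleration at a common rate (units of g or m/s^2)."""

    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.acc_x = np.asarray(self.acc_x, dtype=float)
        self.acc_y = np.asarray(self.acc_y, dtype=float)
        self.acc_z = np.asarray(self.acc_z, dtype=float)
        if not (self.acc_x.size == self.acc_y.size == self.acc_z.size):
            raise ValidationError("accelerometer axes must have equal lengths")

    @property
    def n_samples(self) -> int:
        return self.acc_x.size

    @classmethod
    def from_channels(cls, x: TimeSeriesChannel, y: TimeSeriesChannel,
                      z: TimeSeriesChannel) -> "AccelFrame":
        return cls(x.samples, y.samples, z.samples, x.sampling_rate)


@dataclass
class CycleSegmentation:
    cycle_bounds: list[tuple[float, float]]   # (start_s, end_s) per cycle
    n_cycles: int
    reliable: bool = True                     # False when no stable periodicity

    def __post_init__(self) -> None:
        if self.n_cycles != len(self.cycle_bounds):
            raise ValidationError("n_cycles must equal len(cycle_bounds)")


def accel_preprocess(frame: AccelFrame, params: AccelParams | None = None) -> AccelFrame:
    """Zero-phase band-pass then centred moving-average smoothing, per axis."""
    params = params or AccelParams()
    low, high = params.band_hz
    if not (0 < low < high):
        raise ValidationError(f"invalid band [{low}, {high}]")
    if frame.sampling_rate <= 2 * high:
        raise ValidationError("sampling rate too low for the accelerometer band")
    sos = sps.butter(params.order, [low, high], btype="bandpass",
                     fs=frame.sampling_rate, output="sos")
    win = max(int(round(params.smooth_s * frame.sampling_rate)), 1)

    def clean(a: np.ndarray) -> np.ndarray:
        return uniform_filter1d(sps.sosfiltfilt(sos, a), size=win, mode="nearest")

    return AccelFrame(clean(frame.acc_x), clean(frame.acc_y), clean(frame.acc_z),
                      frame.sampling_rate)


def _merge_short_segments(bounds: list[tuple[int, int]], min_frac: float) -> list[tuple[int, int]]:
    """Merge segments shorter than ``min_frac`` of the median length into a neighbour."""
    bounds = list(bounds)
    while len(bounds) > 1:
        lengths = np.array([b - a for a, b in bounds], dtype=float)
        floor_len = min_frac * float(np.median(lengths))
        short = int(np.argmin(lengths))
        if lengths[short] >= floor_len:
            break
        if short == 0:
            a, b = bounds.pop(0)
            a2, b2 = bounds[0]
            bounds[0] = (a, b2)
        else:
            a, b = bounds.pop(short)
            a2, b2 = bounds[short - 1]
            bounds[short - 1] = (a2, b)
    return bounds


def segment_cycles(y: TimeSeriesChannel, params: AccelParams | None = None) -> CycleSegmentation:
    """Segment task cycles from the preprocessed antero-posterior axis.

    Boundaries are phase-wrap events of the z-scored signal's analytic phase;
    partial segments at the trial edges count as cycles only when at least
    half the median cycle length.  A flat signal yields zero cycles; when the
    segmented cycle durations are too irregular to indicate a periodic task
    (duration CV > 0.5), ``reliable`` is False.
    """
    params = params or AccelParams()
    x = y.samples
    sd = float(np.std(x))
    if sd == 0 or x.size < 8:
        log.warning("flat accelerometer signal: zero cycles")
        return CycleSegmentation([], 0, reliable=False)
    phase = discrete_hilbert((x - np.mean(x)) / sd, y.sampling_rate).phase
    # wrap events: phase falls by ~2*pi between consecutive samples
    wraps = np.flatnonzero(np.diff(phase) < -np.pi) + 1
    if wraps.size == 0:
        log.warning("no phase wraps found: zero cycles")
        return CycleSegmentation([], 0, reliable=False)
    edges = [0, *wraps.tolist(), x.size]
    segments = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)
                if edges[i + 1] > edges[i]]
    interior = segments[1:-1] if len(segments) > 2 else []
    if interior:
        interior = _merge_short_segments(interior, params.min_cycle_frac)
        median_len = float(np.median([b - a for a, b in interior]))
    else:
        median_len = float(np.median([b - a for a, b in segments]))
    # edge partials count as cycles when >= half the median cycle length
    kept = list(interior)
    edge_segs = [segments[0]] if len(segments) == 1 else [segments[0], segments[-1]]
    for seg in edge_segs:
        if seg[1] - seg[0] >= 0.5 * median_len:
            kept.append(seg)
    kept.sort()
    rate = y.sampling_rate
    bounds = [(a / rate, b / rate) for a, b in kept]
    durations = np.array([b - a for a, b in bounds])
    # fewer than 3 cycles is not evidence of a periodic task
    reliable = bool(durations.size >= 3
                    and np.std(durations) / np.mean(durations) <= 0.5)
    return CycleSegmentation(bounds, len(bounds), reliable=reliable)


def pitch(frame: AccelFrame) -> np.ndarray:
    """Pitch angle per sample, degrees in (-90, 90); undefined samples are NaN."""
    denom = np.hypot(frame.acc_y, frame.acc_z)
    out = np.full(frame.n_samples, np.nan)
    ok = denom > 0
    out[ok] = np.degrees(np.arctan(-frame.acc_x[ok] / denom[ok]))
    return out


def roll(frame: AccelFrame) -> np.ndarray:
    """Roll angle per sample, degrees; acc_z = 0 gives +/-90 by sign of acc_y."""
    out = np.full(frame.n_samples, np.nan)
    z_ok = frame.acc_z != 0
    out[z_ok] = np.degrees(np.arctan(frame.acc_y[z_ok] / frame.acc_z[z_ok]))
    z_zero = ~z_ok & (frame.acc_y != 0)
    out[z_zero] = 90.0 * np.sign(frame.acc_y[z_zero])
    return out


def angle_summary(angles: np.ndarray, kind: str = "mad") -> float:
    """Per-trial amplitude summary of an angle series (NaNs excluded)."""
    a = angles[~np.isnan(angles)]
    if a.size == 0:
        return float("nan")
    if kind == "mad":
        return float(np.mean(np.abs(a - np.mean(a))))
    if kind == "sd":
        return float(np.std(a))
    if kind == "range":
        return float(np.ptp(a))
    raise ValidationError(f"unknown angle summary {kind!r}")


def smooth_only(frame: AccelFrame, params: AccelParams | None = None) -> AccelFrame:
    """Moving-average smoothing without the band-pass (gravity retained)."""
    params = params or AccelParams()
    win = max(int(round(params.smooth_s * frame.sampling_rate)), 1)

    def sm(a: np.ndarray) -> np.ndarray:
        return uniform_filter1d(a, size=win, mode="nearest")

    return AccelFrame(sm(frame.acc_x), sm(frame.acc_y), sm(frame.acc_z),
                      frame.sampling_rate)


def accel_trial_summary(frame: AccelFrame, trial: Annotation | None = None,
                        params: AccelParams | None = None
                        ) -> tuple[int, float, float]:
    """(n_cycles, pitch amplitude, roll amplitude) for one raw trial frame.

    Cycles are segmented on the fully preprocessed (band-passed + smoothed)
    antero-posterior axis; the tilt angles are computed on the smoothed-only
    frame, since the arctangent formulas need the gravity component the
    band-pass removes.
    """
    params = params or AccelParams()
    pre = accel_preprocess(frame, params)
    y = TimeSeriesChannel("acc_y", pre.acc_y, pre.sampling_rate)
    seg = segment_cycles(y, params)
    tilt = smooth_only(frame, params)
    p = angle_summary(pitch(tilt), params.angle_summary)
    r = angle_summary(roll(tilt), params.angle_summary)
    return seg.n_cycles, p, r
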