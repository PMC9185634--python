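"""Core data types and file I/O shared by every pipeline stage.

A :class:`Recording` holds one subject's uniformly sampled channels
(RIP chest/abdomen, surface EMG, triaxial wrist accelerometer — all at a
single acquisition rate, 1000 Hz by default) together with trial / rest /
MVC annotations.  Recordings are stored on disk as a delimited-text file of
channel columns plus a JSON sidecar of subject metadata and annotations;
samples round-trip bit-exactly.

Time intervals are half-open ``[start_s, end_s)``; the sample index range
of an annotation is ``floor(start_s * rate)`` inclusive to
``floor(end_s * rate)`` exclusive, so adjacent annotations never share a
sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesChannel",
    "Annotation",
    "Recording",
    "DecileTable",
    "FormatError",
    "ValidationError",
    "read_recording",
    "write_recording",
    "slice_annotation",
    "decile_spans",
]

TRIALS = ("Baseline", "Fatigue 1", "Fatigue 2")

#: channels each processing stage requires
STAGE_CHANNELS = {
    "rip": ("rip_chest", "rip_abdomen"),
    "emg": ("emg_biceps", "emg_trapezius"),
    "accel": ("acc_x", "acc_y", "acc_z"),
}


class FormatError(RuntimeError):
    """Raised when an on-disk recording is malformed or incomplete."""


class ValidationError(ValueError):
    """Raised when data violate a structural invariant."""


@dataclass
class TimeSeriesChannel:
    """A uniformly sampled scalar signal with rate and unit metadata."""

    label: str
    samples: np.ndarray
    sampling_rate: float
    unit: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError(f"channel {self.label!r}: samples must be a non-empty 1-D sequence")
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ValidationError(f"channel {self.label!r}: sampling_rate must be a positive real")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def replace(self, samples: np.ndarray, sampling_rate: float | None = None,
                label: str | None = None) -> "TimeSeriesChannel":
        return TimeSeriesChannel(
            label=self.label if label is None else label,
            samples=samples,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            unit=self.unit,
        )


@dataclass(frozen=True)
class Annotation:
    """A labelled half-open time span: a trial, a rest period, or an MVC bout."""

    kind: str  # "trial" | "rest" | "mvc"
    name: str
    start_s: float
    end_s: float

    KINDS = ("trial", "rest", "mvc")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"annotation kind must be one of {self.KINDS}, got {self.kind!r}")
        if not (0 <= self.start_s < self.end_s):
            raise ValidationError(
                f"annotation {self.name!r}: need 0 <= start < end, got [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Recording:
    """One subject's channel set plus trial/MVC/rest annotations."""

    subject_id: str
    channels: dict[str, TimeSeriesChannel]
    annotations: list[Annotation] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("recording must contain at least one channel")
        dur = self.duration_s
        for ann in self.annotations:
            if ann.end_s > dur + 1e-9:
                raise ValidationError(
                    f"annotation {ann.name!r} ends at {ann.end_s} s but recording lasts {dur:.6f} s")
        trials = sorted(self.trial_annotations(), key=lambda a: a.start_s)
        for a, b in zip(trials, trials[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValidationError(f"trial annotations {a.name!r} and {b.name!r} overlap")

    @property
    def duration_s(self) -> float:
        return min(ch.duration_s for ch in self.channels.values())

    def trial_annotations(self) -> list[Annotation]:
        return [a for a in self.annotations if a.kind == "trial"]

    def mvc_annotations(self, muscle: str | None = None) -> list[Annotation]:
        anns = [a for a in self.annotations if a.kind == "mvc"]
        if muscle is not None:
            anns = [a for a in anns if a.name == muscle]
        return anns

    def require_channels(self, stage: str) -> None:
        """Check the channels a pipeline stage needs are present."""
        missing = [c for c in STAGE_CHANNELS[stage] if c not in self.channels]
        if missing:
            raise ValidationError(
                f"subject {self.subject_id!r}: stage {stage!r} requires missing channel(s) {missing}")


def _sample_span(ann: Annotation, rate: float) -> tuple[int, int]:
    # floor(start*rate) inclusive .. floor(end*rate) exclusive; round() guards
    # float representation of exact products like 600 * 40.
    lo = int(np.floor(round(ann.start_s * rate, 9)))
    hi = int(np.floor(round(ann.end_s * rate, 9)))
    return lo, hi


def slice_annotation(rec: Recording, ann: Annotation) -> Recording:
    """Restrict a recording to one annotation's half-open span, time origin at 0.

    Channels keep their sampling rate and labels; annotations other than
    ``ann`` are dropped (they belong to the parent timeline).
    """
    channels: dict[str, TimeSeriesChannel] = {}
    for label, ch in rec.channels.items():
        lo, hi = _sample_span(ann, ch.sampling_rate)
        if hi > ch.samples.size:
            raise ValidationError(f"annotation {ann.name!r} exceeds channel {label!r}")
        channels[label] = ch.replace(samples=ch.samples[lo:hi])
    return Recording(
        subject_id=rec.subject_id,
        channels=channels,
        annotations=[Annotation(ann.kind, ann.name, 0.0, ann.duration_s)],
        metadata=dict(rec.metadata),
    )


def slice_span(ch: TimeSeriesChannel, start_s: float, end_s: float) -> TimeSeriesChannel:
    """Half-open slice of a single channel."""
    lo, hi = _sample_span(Annotation("rest", "span", start_s, end_s), ch.sampling_rate)
    return ch.replace(samples=ch.samples[lo:hi])


def decile_spans(duration_s: float, rate: float, n: int = 10) -> list[tuple[int, int]]:
    """Partition ``[0, duration)`` into ``n`` contiguous sample spans.

    The spans are pairwise disjoint and their union is exactly the trial:
    boundaries at ``floor(i * total / n)``.
    """
    total = int(np.floor(round(duration_s * rate, 9)))
    edges = [(i * total) // n for i in range(n + 1)]
    return [(edges[i], edges[i + 1]) for i in range(n)]


# ---------------------------------------------------------------------------
# DecileTable

class DecileTable:
    """Long-format (subject, trial, division 1-10, metric, value) records.

    Thin wrapper around a pandas DataFrame enforcing the schema every
    statistical model consumes.
    """

    COLUMNS = ("subject_id", "trial", "division", "metric", "value")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"DecileTable missing columns {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["division"] = df["division"].astype(int)
        if not df["division"].between(1, 10).all():
            raise ValidationError("division must lie in [1, 10]")
        dup = df.duplicated(subset=["subject_id", "trial", "division", "metric"])
        if dup.any():
            raise ValidationError("duplicate (subject, trial, division, metric) rows")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "DecileTable":
        return cls(pd.DataFrame.from_records(list(records)))

    def pivot_metrics(self) -> pd.DataFrame:
        """Wide layout: one row per (subject, trial, division), one column per metric."""
        return (self.df.pivot_table(index=["subject_id", "trial", "division"],
                                    columns="metric", values="value", aggfunc="first")
                .reset_index())

    def metrics(self) -> list[str]:
        return sorted(self.df["metric"].unique())

    def merge(self, other: "DecileTable") -> "DecileTable":
        return DecileTable(pd.concat([self.df, other.df], ignore_index=True))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "DecileTable":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Recording I/O: delimited text + JSON sidecar

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path) -> Path:
    """Write a recording as ``<path>.csv`` + ``<path>.json`` sidecar.

    All channels must share one sampling rate (the acquisition rate);
    samples are printed with 17 significant digits so float64 values
    round-trip bit-exactly.
    """
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    rates = {ch.sampling_rate for ch in rec.channels.values()}
    if len(rates) != 1:
        raise FormatError("on-disk recordings require a single common sampling rate")
    lengths = {ch.samples.size for ch in rec.channels.values()}
    if len(lengths) != 1:
        raise FormatError("on-disk recordings require equal-length channels")
    labels = list(rec.channels)
    data = np.column_stack([rec.channels[c].samples for c in labels])
    header = ",".join(labels)
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.17g")
    sidecar = {
        "subject_id": rec.subject_id,
        "sampling_rate": rates.pop(),
        "units": {c: rec.channels[c].unit for c in labels},
        "metadata": rec.metadata,
        "annotations": [
            {"kind": a.kind, "name": a.name, "start_s": a.start_s, "end_s": a.end_s}
            for a in rec.annotations
        ],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing annotation sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
        rate = float(meta["sampling_rate"])
        subject = str(meta["subject_id"])
    except (json.JSONDecodeError, KeyError) as exc:
        raise FormatError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    frame = pd.read_csv(path, dtype=np.float64, float_precision="round_trip")
    if frame.empty:
        raise FormatError(f"{path} holds no samples")
    units = meta.get("units", {})
    channels = {
        label: TimeSeriesChannel(label, frame[label].to_numpy(), rate, units.get(label, ""))
        for label in frame.columns
    }
    annotations = [
        Annotation(a["kind"], a["name"], float(a["start_s"]), float(a["end_s"]))
        for a in meta.get("annotations", [])
    ]
    return Recording(subject_id=subject, channels=channels,
                     annotations=annotations, metadata=meta.get("metadata", {}))


def read_study(directory) -> list[Recording]:
    """Read every recording in a study directory (sorted by file name)."""
    directory = Path(directory)
    recs = [read_recording(p) for p in sorted(directory.glob("*.csv"))
            if _sidecar_path(p).exists()]
    if not recs:
        raise FormatError(f"no recordings found under {directory}")
    return recs
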