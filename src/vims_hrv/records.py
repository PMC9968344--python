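"""Core data containers: ECG records, beat annotations and RR series.

These are deliberately thin, validated dataclasses; the heavy lifting lives in
the processing modules.  An :class:`RRSeries` is the central HRV substrate:
an irregularly sampled tachogram where ``beat_times[i]`` is the time of the
*second* beat of interval ``i`` and ``rr_ms[i]`` the interval length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError

# Event kinds used in the sidecar event stream.
SECTION_START = "section_start"
RATING = "rating"
PREMATURE_STOP = "premature_stop"

SECTIONS = ("baseline", "nausea", "recovery")


@dataclass(frozen=True)
class Event:
    """A timestamped annotation: section boundary, nausea rating or stop."""

    time_s: float
    kind: str
    value: object = None

    def to_dict(self) -> dict:
        return {"time_s": float(self.time_s), "kind": self.kind, "value": self.value}

    @classmethod
    def from_dict(cls, d: dict) -> "Event":
        return cls(time_s=float(d["time_s"]), kind=str(d["kind"]), value=d.get("value"))


def events_to_json(events: Iterable[Event], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([e.to_dict() for e in events], indent=1) + "\n", encoding="utf-8"
    )


def events_from_json(path: str | Path) -> list[Event]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return [Event.from_dict(d) for d in data]


@dataclass
class ECGRecord:
    """Single-channel ECG voltage trace with annotations.

    Parameters
    ----------
    samples : microvolts, shape (n,)
    fs : sampling rate in Hz
    start_time : time of the first sample, seconds
    events : section boundaries / ratings / stop markers
    r_peak_times : optional ground-truth R-peak times (synthetic records)
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    events: list[Event] = field(default_factory=list)
    r_peak_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.samples.ndim != 1:
            raise ParameterError("samples must be one-dimensional")
        span = (self.start_time, self.start_time + self.duration)
        for ev in self.events:
            if not (span[0] - 1e-9 <= ev.time_s <= span[1] + 1e-9):
                raise ParameterError(
                    f"event at t={ev.time_s:.3f}s lies outside the record span {span}"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class BeatAnnotations:
    """Detected R-peaks as sample indices + times; strictly increasing."""

    r_peak_indices: np.ndarray
    r_peak_times: np.ndarray
    refractory_s: float = 0.2

    def __post_init__(self) -> None:
        self.r_peak_indices = np.asarray(self.r_peak_indices, dtype=int)
        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)
        if self.r_peak_indices.size != self.r_peak_times.size:
            raise ParameterError("indices and times must have equal length")
        if self.r_peak_times.size > 1:
            gaps = np.diff(self.r_peak_times)
            if np.any(gaps <= 0):
                raise ParameterError("R-peak times must be strictly increasing")
            if np.any(gaps < self.refractory_s - 1e-9):
                raise ParameterError(
                    "R-peaks closer than the refractory period "
                    f"({self.refractory_s*1e3:.0f} ms)"
                )

    def __len__(self) -> int:
        return self.r_peak_times.size


# Physiological plausibility gate on retained RR intervals (ms).
RR_MIN_MS = 300.0
RR_MAX_MS = 2000.0


@dataclass
class RRSeries:
    """Irregular beat-to-beat interval series.

    ``quality_flags[i]`` is True when interval ``i`` is considered an artifact
    and must be excluded from spectral estimation (it is retained for audit).
    """

    beat_times: np.ndarray
    rr_ms: np.ndarray
    quality_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.beat_times.size != self.rr_ms.size:
            raise ParameterError("beat_times and rr_ms must have equal length")
        if np.any(self.rr_ms <= 0):
            raise ParameterError("RR intervals must be positive")
        if self.quality_flags is None:
            self.quality_flags = np.zeros(self.rr_ms.size, dtype=bool)
        else:
            self.quality_flags = np.asarray(self.quality_flags, dtype=bool)
            if self.quality_flags.size != self.rr_ms.size:
                raise ParameterError("quality_flags length mismatch")
        clean = self.rr_ms[~self.quality_flags]
        if clean.size and (np.any(clean < RR_MIN_MS) or np.any(clean > RR_MAX_MS)):
            raise ParameterError(
                "retained RR intervals must lie within the physiological gate "
                f"[{RR_MIN_MS:.0f}, {RR_MAX_MS:.0f}] ms; flag outliers first"
            )

    def __len__(self) -> int:
        return self.rr_ms.size

    @property
    def clean(self) -> tuple[np.ndarray, np.ndarray]:
        """(beat_times, rr_ms) of unflagged intervals."""
        keep = ~self.quality_flags
        return self.beat_times[keep], self.rr_ms[keep]

    def slice(self, t0: float, t1: float) -> "RRSeries":
        """Intervals whose terminating beat falls in the half-open [t0, t1)."""
        keep = (self.beat_times >= t0) & (self.beat_times < t1)
        return RRSeries(
            beat_times=self.beat_times[keep],
            rr_ms=self.rr_ms[keep],
            quality_flags=self.quality_flags[keep],
        )

    def shifted(self, dt: float) -> "RRSeries":
        return replace(self, beat_times=self.beat_times + dt)


def rr_to_csv(rr: RRSeries, path: str | Path) -> None:
    """Two-column CSV: beat_time_s, rr_ms (flagged intervals included)."""
    arr = np.column_stack([rr.beat_times, rr.rr_ms])
    header = "beat_time_s,rr_ms"
    np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.6f")


def rr_from_csv(path: str | Path) -> RRSeries:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return RRSeries(beat_times=arr[:, 0], rr_ms=arr[:, 1])


def section_bounds(events: Sequence[Event]) -> dict[str, float]:
    """Map section name -> start time from a session event stream."""
    return {
        str(ev.value): ev.time_s for ev in events if ev.kind == SECTION_START
    }
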