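"""ECG ingest, zero-phase filtering, Pan-Tompkins R-peak detection, RR series
construction and rating-dependent 5-minute epoch extraction.

The Pan-Tompkins detector follows the canonical parameterization: 5-15 Hz
bandpass, five-point derivative, squaring, 150 ms moving-window integration,
adaptive signal/noise thresholds with search-back, a 200 ms refractory period
and a 360 ms T-wave slope check.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import (
    FormatError,
    InsufficientDataError,
    MissingChannelError,
    ParameterError,
    TruncationError,
)
from .records import (
    PREMATURE_STOP,
    RATING,
    RR_MAX_MS,
    RR_MIN_MS,
    BeatAnnotations,
    ECGRecord,
    Event,
    RRSeries,
    events_from_json,
    section_bounds,
)

__all__ = [
    "read_ecg",
    "bandpass_zero_phase",
    "detect_r_peaks",
    "build_rr_series",
    "extract_epoch",
]


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def _sidecar_events(path: Path) -> list[Event]:
    for cand in (
        path.with_suffix(path.suffix + ".events.json"),
        path.with_suffix(".events.json"),
        path.parent / (path.stem.replace("_ecg", "") + "_events.json"),
    ):
        if cand.exists():
            return events_from_json(cand)
    return []


def read_ecg(path: str | Path, format: str | None = None) -> ECGRecord:
    """Read a single-channel ECG from CSV, EDF or BDF (microvolts).

    CSV must have a ``time_s,uv`` header; the sampling rate is inferred from
    the (monotone) time column.  EDF/BDF are read through ``mne``; the first
    channel whose label contains ``ECG`` (else the first channel) is used.
    Events are loaded from a JSON sidecar (``<stem>_events.json`` or
    ``<name>.events.json``) when present.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        try:
            arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"cannot parse CSV ECG {path}: {exc}") from exc
        if arr.shape[1] < 2:
            raise MissingChannelError(f"{path} lacks a voltage column")
        t, uv = arr[:, 0], arr[:, 1]
        dt = np.diff(t)
        if t.size < 2 or np.any(dt <= 0):
            raise FormatError(f"{path}: time column must be strictly increasing")
        fs = 1.0 / float(np.median(dt))
        record = ECGRecord(samples=uv, fs=float(np.round(fs, 6)),
                           start_time=float(t[0]))
    elif fmt in ("edf", "bdf"):
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise FormatError("reading EDF/BDF requires the 'mne' package") from exc
        reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_bdf
        try:
            raw = reader(path, preload=True, verbose="ERROR")
        except Exception as exc:
            raise FormatError(f"cannot parse {fmt.upper()} file {path}: {exc}") from exc
        names = raw.ch_names
        if not names:
            raise MissingChannelError(f"{path} contains no channels")
        picks = [n for n in names if "ecg" in n.lower()] or [names[0]]
        data = raw.get_data(picks=picks[:1])[0] * 1e6  # volts -> microvolts
        record = ECGRecord(samples=data, fs=float(raw.info["sfreq"]))
    else:
        raise FormatError(f"unknown ECG format {fmt!r} (expected edf, bdf or csv)")
    record.events = _sidecar_events(path)
    # re-validate event spans against the actual record
    ECGRecord(samples=record.samples, fs=record.fs,
              start_time=record.start_time, events=record.events)
    return record


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------

def bandpass_zero_phase(
    ecg: ECGRecord, low: float, high: float, order: int = 2
) -> ECGRecord:
    """Forward-backward Butterworth bandpass (zero group delay)."""
    if not (0 < low < high < ecg.fs / 2):
        raise ParameterError(
            f"band ({low}, {high}) Hz invalid for fs={ecg.fs} Hz "
            "(need 0 < low < high < fs/2)"
        )
    sos = signal.butter(order, [low, high], btype="band", fs=ecg.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ecg.samples)
    return ECGRecord(
        samples=filtered,
        fs=ecg.fs,
        start_time=ecg.start_time,
        events=list(ecg.events),
        r_peak_times=ecg.r_peak_times,
    )


# --------------------------------------------------------------------------
# Pan-Tompkins R-peak detection
# --------------------------------------------------------------------------

_REFRACTORY_S = 0.200
_TWAVE_S = 0.360
_INTEGRATION_S = 0.150


def _moving_window_integral(x: np.ndarray, fs: float) -> np.ndarray:
    w = max(1, int(round(_INTEGRATION_S * fs)))
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(ecg: ECGRecord) -> BeatAnnotations:
    """Pan-Tompkins QRS detection on a single-lead ECG.

    Returns annotations with strictly increasing peak times separated by at
    least the 200 ms refractory period.  On a record where nothing crosses
    the adaptive thresholds, an empty annotation set is returned together
    with a warning (not an exception).
    """
    if ecg.duration < 10.0:
        raise InsufficientDataError(
            f"record of {ecg.duration:.1f} s is shorter than the 10 s minimum"
        )
    fs = ecg.fs
    band = bandpass_zero_phase(ecg, 5.0, 15.0).samples
    # five-point derivative (Pan-Tompkins FIR), zero-phase via centering
    deriv = np.convolve(band, np.array([1, 2, 0, -2, -1]) * (fs / 8.0), mode="same")
    squared = deriv**2
    mwi = _moving_window_integral(squared, fs)

    min_dist = int(round(_REFRACTORY_S * fs))
    peak_idx, _ = signal.find_peaks(mwi, distance=min_dist)
    if peak_idx.size == 0 or not np.any(mwi > 0):
        warnings.warn("no candidate peaks found in record", stacklevel=2)
        return BeatAnnotations(np.array([], int), np.array([], float))

    # threshold initialization from the first 2 s
    init = mwi[: int(2 * fs)]
    spki = 0.25 * float(init.max(initial=0.0))
    npki = 0.5 * float(np.mean(init)) if init.size else 0.0

    qrs: list[int] = []
    noise: list[int] = []
    rr_recent: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    def slope_around(i: int) -> float:
        lo, hi = max(0, i - int(0.075 * fs)), min(len(deriv), i + int(0.075 * fs))
        return float(np.max(np.abs(deriv[lo:hi]))) if hi > lo else 0.0

    def accept(i: int) -> None:
        nonlocal spki
        spki = 0.125 * mwi[i] + 0.875 * spki
        if qrs:
            rr_recent.append((i - qrs[-1]) / fs)
            if len(rr_recent) > 8:
                rr_recent.pop(0)
        qrs.append(i)

    for i in peak_idx:
        if qrs and (i - qrs[-1]) / fs < _REFRACTORY_S:
            continue
        is_qrs = mwi[i] > threshold1()
        if is_qrs and qrs and (i - qrs[-1]) / fs < _TWAVE_S:
            # T-wave check: markedly smaller max slope than the previous QRS
            if slope_around(i) < 0.5 * slope_around(qrs[-1]):
                is_qrs = False
        if is_qrs:
            accept(i)
        else:
            noise.append(i)
            npki = 0.125 * mwi[i] + 0.875 * npki
            # search-back: long gap since last QRS -> revisit with T2 = T1/2
            if qrs and rr_recent:
                rr_avg = float(np.mean(rr_recent))
                if (i - qrs[-1]) / fs > 1.66 * rr_avg:
                    lo = qrs[-1] + min_dist
                    cands = peak_idx[(peak_idx > lo) & (peak_idx < i)]
                    if cands.size:
                        best = cands[np.argmax(mwi[cands])]
                        if mwi[best] > 0.5 * threshold1():
                            accept(int(best))

    if not qrs:
        warnings.warn("no peaks exceeded the adaptive thresholds", stacklevel=2)
        return BeatAnnotations(np.array([], int), np.array([], float))

    # fiducial refinement: R is the extremum of the (zero-phase) bandpassed
    # signal near the integrator peak
    half = int(round(0.100 * fs))
    refined = []
    for i in sorted(set(qrs)):
        lo, hi = max(0, i - half), min(len(band), i + half + 1)
        refined.append(lo + int(np.argmax(band[lo:hi])))
    refined = np.array(sorted(set(refined)), dtype=int)
    # enforce refractoriness after refinement (keep the larger peak)
    keep: list[int] = []
    for i in refined:
        if keep and (i - keep[-1]) / fs < _REFRACTORY_S:
            if band[i] > band[keep[-1]]:
                keep[-1] = int(i)
        else:
            keep.append(int(i))
    idx = np.array(keep, dtype=int)
    times = ecg.start_time + idx / fs
    return BeatAnnotations(r_peak_indices=idx, r_peak_times=times)


# --------------------------------------------------------------------------
# RR series
# --------------------------------------------------------------------------

def build_rr_series(
    beats: BeatAnnotations,
    neighborhood: int = 11,
    deviation_fraction: float = 0.20,
) -> RRSeries:
    """Successive differences of the beat times, with automated artifact flags.

    An interval is flagged when it deviates more than ``deviation_fraction``
    from the median of its ``neighborhood``-interval surroundings, or falls
    outside the 300-2000 ms physiological gate.  Flagged intervals are
    excluded from spectral estimation downstream but retained for audit.
    """
    if len(beats) < 2:
        raise InsufficientDataError("need at least 2 beats to form RR intervals")
    rr_ms = np.diff(beats.r_peak_times) * 1e3
    beat_times = beats.r_peak_times[1:]
    n = rr_ms.size
    half = neighborhood // 2
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        neigh = np.delete(rr_ms[lo:hi], i - lo)
        if neigh.size == 0:
            continue
        med = float(np.median(neigh))
        if med > 0 and abs(rr_ms[i] - med) > deviation_fraction * med:
            flags[i] = True
    flags |= (rr_ms < RR_MIN_MS) | (rr_ms > RR_MAX_MS)
    return RRSeries(beat_times=beat_times, rr_ms=rr_ms, quality_flags=flags)


# --------------------------------------------------------------------------
# Epoch extraction
# --------------------------------------------------------------------------

def extract_epoch(
    rr: RRSeries,
    events: list[Event],
    section: str,
    epoch_len: float = 300.0,
) -> tuple[RRSeries, tuple[float, float]]:
    """Extract the analysis epoch of a section per the rating-dependent rules.

    ``baseline``: the epoch is the (first) ``epoch_len`` seconds of the
    baseline section.  ``nausea``: (a) if the section ran its full course
    with no rating >= 2 (moderate), the window ends at recovery onset;
    (b) if a rating >= 2 occurred, the window ends when the maximum rating
    was first triggered; (c) if the participant stopped the stimulus
    prematurely, the window ends at recovery onset.  Windows are half-open
    ``[start, end)``; a window that would extend before the section start
    raises :class:`TruncationError` with the available duration.

    Returns ``(epoch_rr, (start, end))`` with absolute times.
    """
    bounds = section_bounds(events)
    if section == "baseline":
        if "baseline" not in bounds:
            raise ParameterError("events lack a baseline section_start marker")
        start = bounds["baseline"]
        limit = bounds.get("nausea", start + epoch_len)
        end = min(start + epoch_len, limit)
        return rr.slice(start, end), (start, end)
    if section != "nausea":
        raise ParameterError(f"no epoch rule for section {section!r}")
    if "nausea" not in bounds or "recovery" not in bounds:
        raise ParameterError("events lack nausea/recovery section_start markers")
    nausea_start, recovery_start = bounds["nausea"], bounds["recovery"]
    stops = [e for e in events if e.kind == PREMATURE_STOP]
    ratings = [e for e in events
               if e.kind == RATING and nausea_start <= e.time_s < recovery_start]
    if stops:                      # rule (c)
        end = recovery_start
    elif ratings and max(int(e.value) for e in ratings) >= 2:   # rule (b)
        max_val = max(int(e.value) for e in ratings)
        end = min(e.time_s for e in ratings if int(e.value) == max_val)
    else:                          # rule (a)
        end = recovery_start
    start = end - epoch_len
    if start < nausea_start - 1e-9:
        raise TruncationError(
            f"epoch of {epoch_len:.0f} s ends at t={end:.1f}s but only "
            f"{end - nausea_start:.1f} s of the nauseogenic section are available"
        )
    return rr.slice(start, end), (start, end)
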