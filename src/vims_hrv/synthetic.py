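"""Synthetic ECG / RR / questionnaire generator for the crossover study design.

The study analysed here recorded 14 participants in a two-condition
(sham vs. transauricular electrical stimulation, "tES") within-participant
crossover: each session is 5 min of fixation baseline, up to 20 min of a
nauseogenic optokinetic stimulus, and 5 min of recovery, with keypad nausea
ratings (0-3) logged during the nauseogenic section.  The recordings
themselves are not deposited, so this module generates sessions with the
statistical structure the downstream analysis assumes:

* Beat times come from an integral pulse frequency modulation (IPFM) model:
  a modulated instantaneous rate ``(1 + m(t)) / mean_rr`` is integrated, and
  a beat is emitted each time the integral crosses an integer.  Band-limited
  sinusoidal modulation at ``f_lf`` (default 0.10 Hz) and ``f_hf`` (default
  0.25 Hz) maps directly onto the LF (0.04-0.15 Hz) and HF (0.15-0.40 Hz)
  bands of the RR spectrum, which is exactly what the spectral and
  time-frequency stages estimate.
* Motion sickness is emulated as an autonomic-balance shift during the
  nauseogenic section: HF modulation amplitude down, LF up, relative to
  baseline.  The tES condition attenuates that shift.
* Nausea-rating latencies are drawn from truncated normals whose means/SDs
  follow the published per-condition latency table (minutes to mild /
  moderate / strong), longer under tES.
* MSAQ item responses (16 items, 1-9) come from a latent-normal model with a
  condition-dependent post-session shift, discretized to the ordinal scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import signal

from .errors import ConfigurationError, ParameterError
from .records import (
    PREMATURE_STOP,
    RATING,
    SECTION_START,
    ECGRecord,
    Event,
    RRSeries,
    events_to_json,
    rr_to_csv,
)

CONDITIONS = ("sham", "tes")
ORDERS = ("sham->tes", "tes->sham")

# Internal integration grid for the IPFM integrator (Hz).  Beat-time error
# after linear interpolation of the integer crossing is O(dt^2) ~ 0.1 ms.
_IPFM_GRID_FS = 64.0


# --------------------------------------------------------------------------
# IPFM heartbeat model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IPFMParams:
    """Parameters of the IPFM beat generator.

    ``a_lf``/``a_hf`` are dimensionless modulation amplitudes of the
    instantaneous heart rate; ``broadband_sd`` is the SD of low-pass
    (< 0.4 Hz) filtered broadband modulation noise.  The stability invariant
    ``a_lf + a_hf + 3*broadband_sd < 1`` keeps the modulated rate positive.
    """

    mean_rr: float = 0.85
    a_lf: float = 0.04
    f_lf: float = 0.10
    a_hf: float = 0.08
    f_hf: float = 0.25
    broadband_sd: float = 0.01
    duration: float = 300.0
    seed: int = 0

    def validate(self) -> None:
        if not self.mean_rr > 0:
            raise ParameterError("mean_rr must be positive")
        for name in ("a_lf", "a_hf"):
            v = getattr(self, name)
            if not 0 <= v <= 0.5:
                raise ParameterError(f"{name} must lie in [0, 0.5]")
        if self.broadband_sd < 0:
            raise ParameterError("broadband_sd must be non-negative")
        if not self.a_lf + self.a_hf + 3 * self.broadband_sd < 1:
            raise ParameterError(
                "a_lf + a_hf + 3*broadband_sd must be < 1 "
                "(modulation would drive the heart rate non-positive)"
            )
        if not self.duration > 2 * self.mean_rr:
            raise ParameterError("duration must exceed two mean RR intervals")


def _broadband_noise(n: int, grid_fs: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """White noise low-pass filtered below 0.4 Hz, rescaled to the target SD."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = signal.butter(4, 0.4, btype="low", fs=grid_fs, output="sos")
    filt = signal.sosfiltfilt(sos, white)
    s = filt.std()
    if s > 0:
        filt = filt * (sd / s)
    return filt


def _ipfm_beats(
    duration: float,
    mean_rr: float,
    modulation: np.ndarray,
    grid_fs: float = _IPFM_GRID_FS,
) -> np.ndarray:
    """Beat times (including t=0) from integrating (1+m(t))/mean_rr."""
    dt = 1.0 / grid_fs
    rate = (1.0 + modulation) / mean_rr
    # integral of the rate on the grid; integ[0] = 0 at t = 0
    integ = np.concatenate([[0.0], np.cumsum(rate) * dt])
    t_grid = np.arange(integ.size) * dt
    n_beats = int(np.floor(integ[-1]))
    if n_beats < 1:
        raise ParameterError("duration too short: no beat emitted")
    thresholds = np.arange(1, n_beats + 1, dtype=float)
    idx = np.searchsorted(integ, thresholds)
    # linear interpolation of the crossing inside grid cell [idx-1, idx]
    i0 = idx - 1
    frac = (thresholds - integ[i0]) / (integ[idx] - integ[i0])
    crossings = t_grid[i0] + frac * dt
    return np.concatenate([[0.0], crossings])


def simulate_rr_ipfm(params: IPFMParams) -> RRSeries:
    """Simulate an RR series with the IPFM model.

    The returned ``beat_times`` are the crossing times (the second beat of
    each interval); an initial beat at t=0 anchors the first interval.
    Deterministic under a fixed ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(np.round(params.duration * _IPFM_GRID_FS))
    t = np.arange(n) / _IPFM_GRID_FS
    m = (
        params.a_lf * np.sin(2 * np.pi * params.f_lf * t)
        + params.a_hf * np.sin(2 * np.pi * params.f_hf * t)
        + _broadband_noise(n, _IPFM_GRID_FS, params.broadband_sd, rng)
    )
    beats = _ipfm_beats(params.duration, params.mean_rr, m)
    rr_ms = np.diff(beats) * 1e3
    return RRSeries(beat_times=beats[1:], rr_ms=rr_ms)


def _ipfm_session(
    mean_rr: float,
    duration: float,
    a_lf_env: np.ndarray,
    a_hf_env: np.ndarray,
    f_lf: float,
    f_hf: float,
    broadband_sd: float,
    rng: np.random.Generator,
) -> RRSeries:
    """IPFM run with piecewise (time-varying) modulation amplitudes."""
    n = a_lf_env.size
    t = np.arange(n) / _IPFM_GRID_FS
    m = (
        a_lf_env * np.sin(2 * np.pi * f_lf * t)
        + a_hf_env * np.sin(2 * np.pi * f_hf * t)
        + _broadband_noise(n, _IPFM_GRID_FS, broadband_sd, rng)
    )
    beats = _ipfm_beats(duration, mean_rr, m)
    return RRSeries(beat_times=beats[1:], rr_ms=np.diff(beats) * 1e3)


# --------------------------------------------------------------------------
# ECG synthesis
# --------------------------------------------------------------------------

# PQRST template: Gaussian bumps (center offset s, width s, amplitude uV).
_ECG_TEMPLATE = (
    (-0.20, 0.025, 120.0),   # P
    (0.00, 0.012, 1000.0),   # R (dominant)
    (-0.025, 0.010, -150.0), # Q
    (0.035, 0.012, -200.0),  # S
    (0.30, 0.050, 250.0),    # T
)
_TEMPLATE_HALF_SPAN = 0.45  # seconds of support on each side of R


def _template(t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for mu, sig, amp in _ECG_TEMPLATE:
        out += amp * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    return out


def synthesize_ecg(
    rr: RRSeries,
    fs: float = 256.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    events: list[Event] | None = None,
    duration: float | None = None,
) -> ECGRecord:
    """Render an RR series as a sampled single-channel ECG.

    A fixed PQRST template (sum of Gaussian bumps, R amplitude dominant) is
    placed at every beat time, sampled at ``fs`` and white noise of SD
    ``noise_sd`` microvolts added.  Ground-truth R-peak times are stored on
    the record for detector round-trips.
    """
    if fs < 128:
        raise ParameterError("fs must be >= 128 Hz to resolve the QRS complex")
    if len(rr) == 0:
        raise ParameterError("rr series is empty")
    beat_times = np.concatenate([[rr.beat_times[0] - rr.rr_ms[0] / 1e3], rr.beat_times])
    if duration is None:
        duration = beat_times[-1] + 0.5
    n = int(np.round(duration * fs))
    samples = np.zeros(n)
    half = int(np.ceil(_TEMPLATE_HALF_SPAN * fs))
    for bt in beat_times:
        c = int(np.round(bt * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        tt = np.arange(lo, hi) / fs - bt
        samples[lo:hi] += _template(tt)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, size=n)
    return ECGRecord(
        samples=samples,
        fs=fs,
        events=list(events or []),
        r_peak_times=beat_times.copy(),
    )


def noise_sd_for_snr(rr: RRSeries, fs: float, snr_db: float) -> float:
    """White-noise SD (uV) giving the requested SNR against the clean ECG power."""
    clean = synthesize_ecg(rr, fs=fs, noise_sd=0.0)
    p_sig = float(np.mean(clean.samples**2))
    return float(np.sqrt(p_sig / 10 ** (snr_db / 10.0)))


# --------------------------------------------------------------------------
# Study-level simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AutonomicTrajectory:
    """Piecewise autonomic schedule of one session.

    ``sections`` maps section name -> (start_s, a_lf, a_hf); sections are
    contiguous and non-overlapping, baseline and recovery last 300 s, the
    nauseogenic section at most 1200 s.  ``rating_events`` carry the keypad
    ratings (non-decreasing); ``premature_stop`` is the stop time if the
    participant quit the nauseogenic stimulus early.
    """

    sections: tuple[tuple[str, float, float, float], ...]
    nausea_duration: float
    rating_events: tuple[tuple[float, int], ...] = ()
    premature_stop: float | None = None

    def __post_init__(self) -> None:
        names = [s[0] for s in self.sections]
        if names != ["baseline", "nausea", "recovery"]:
            raise ParameterError("sections must be baseline, nausea, recovery in order")
        starts = [s[1] for s in self.sections]
        if starts[0] != 0.0 or starts[1] != 300.0:
            raise ParameterError("baseline must last exactly 300 s")
        if not 0 < self.nausea_duration <= 1200.0:
            raise ParameterError("nauseogenic section must last at most 1200 s")
        if abs(starts[2] - (300.0 + self.nausea_duration)) > 1e-9:
            raise ParameterError("sections must be contiguous")
        ratings = [r for _, r in self.rating_events]
        if any(b < a for a, b in zip(ratings, ratings[1:])):
            raise ParameterError("ratings must be non-decreasing in time")

    @property
    def total_duration(self) -> float:
        return 300.0 + self.nausea_duration + 300.0

    def events(self) -> list[Event]:
        evs = [
            Event(0.0, SECTION_START, "baseline"),
            Event(300.0, SECTION_START, "nausea"),
            Event(300.0 + self.nausea_duration, SECTION_START, "recovery"),
        ]
        evs += [Event(t, RATING, int(r)) for t, r in self.rating_events]
        if self.premature_stop is not None:
            evs.append(Event(self.premature_stop, PREMATURE_STOP, None))
        return sorted(evs, key=lambda e: e.time_s)


@dataclass(frozen=True)
class EffectSpec:
    """Condition-effect specification driving :func:`simulate_study`.

    ``modulation[(section, condition)]`` gives the (a_lf, a_hf) amplitudes.
    ``msaq_shift[condition]`` is the post-session latent shift on the 1-9
    item scale.  ``rating_latency_min[condition][rating]`` is the
    (mean, sd) in minutes of the truncated-normal latency to that rating,
    relative to nauseogenic-stimulus onset.
    """

    mean_rr: float = 0.85
    f_lf: float = 0.10
    f_hf: float = 0.25
    broadband_sd: float = 0.012
    modulation: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("baseline", "sham"): (0.040, 0.080),
            ("baseline", "tes"): (0.040, 0.080),
            ("nausea", "sham"): (0.060, 0.040),   # HF halved, LF up
            ("nausea", "tes"): (0.044, 0.072),    # tES attenuates the shift
            ("recovery", "sham"): (0.040, 0.080),
            ("recovery", "tes"): (0.040, 0.080),
        }
    )
    msaq_shift: Mapping[str, float] = field(
        default_factory=lambda: {"sham": 1.5, "tes": 0.5}
    )
    # per-condition latency table (minutes): rating -> (mean, sd)
    rating_latency_min: Mapping[str, Mapping[int, tuple[float, float]]] = field(
        default_factory=lambda: {
            "sham": {1: (6.6, 4.6), 2: (8.6, 5.9), 3: (10.8, 6.1)},
            "tes": {1: (6.3, 5.1), 2: (10.5, 6.7), 3: (12.3, 5.4)},
        }
    )
    premature_stop_prob: Mapping[str, float] = field(
        default_factory=lambda: {"sham": 0.30, "tes": 0.15}
    )
    # between-participant variability
    participant_rr_sd: float = 0.06
    participant_amp_log_sd: float = 0.15
    participant_f_hf_sd: float = 0.015
    # coupling between a participant's tolerance and HF tone / latencies
    tolerance_latency_min_per_sd: float = 2.0
    tolerance_hf_log_gain: float = 0.15

    def validate(self) -> None:
        for section in ("baseline", "nausea", "recovery"):
            for cond in CONDITIONS:
                if (section, cond) not in self.modulation:
                    raise ConfigurationError(
                        f"effect spec missing modulation cell ({section!r}, {cond!r})"
                    )
        for cond in CONDITIONS:
            if cond not in self.msaq_shift:
                raise ConfigurationError(f"effect spec missing msaq_shift[{cond!r}]")
            if cond not in self.rating_latency_min:
                raise ConfigurationError(
                    f"effect spec missing rating_latency_min[{cond!r}]"
                )

    @classmethod
    def null(cls) -> "EffectSpec":
        """Zero-effect spec: sham == tES and nausea == baseline everywhere."""
        amp = (0.040, 0.080)
        lat = {1: (6.5, 4.8), 2: (9.5, 6.3), 3: (11.5, 5.8)}
        return cls(
            modulation={(s, c): amp for s in SECTION_NAMES for c in CONDITIONS},
            msaq_shift={"sham": 1.0, "tes": 1.0},
            rating_latency_min={"sham": lat, "tes": lat},
            premature_stop_prob={"sham": 0.2, "tes": 0.2},
            tolerance_latency_min_per_sd=0.0,
            tolerance_hf_log_gain=0.0,
        )


SECTION_NAMES = ("baseline", "nausea", "recovery")


@dataclass
class MSAQResponse:
    """One questionnaire administration (16 ordinal items, 1-9)."""

    item_scores: np.ndarray
    timing: str  # "pre" | "post"
    participant: str
    condition: str

    def __post_init__(self) -> None:
        self.item_scores = np.asarray(self.item_scores, dtype=int)
        if self.item_scores.size != 16:
            raise ParameterError("MSAQ has exactly 16 items")
        if np.any((self.item_scores < 1) | (self.item_scores > 9)):
            raise ParameterError("MSAQ items are rated 1-9")
        if self.timing not in ("pre", "post"):
            raise ParameterError("timing must be 'pre' or 'post'")


@dataclass
class SessionRecording:
    """One session of one participant: RR ground truth + annotations."""

    participant: str
    condition: str
    trajectory: AutonomicTrajectory
    rr: RRSeries
    seed: int

    @property
    def events(self) -> list[Event]:
        return self.trajectory.events()

    def ecg(self, fs: float = 256.0, noise_sd: float = 10.0) -> ECGRecord:
        """Render the session as ECG (synthesized lazily; deterministic)."""
        return synthesize_ecg(
            self.rr,
            fs=fs,
            noise_sd=noise_sd,
            seed=self.seed ^ 0x5EC5,
            events=self.events,
            duration=self.trajectory.total_duration,
        )


@dataclass
class Participant:
    id: str
    order: str
    sessions: dict[str, SessionRecording]
    msaq: dict[str, dict[str, MSAQResponse]]  # condition -> {"pre","post"}


@dataclass
class StudyDataset:
    participants: list[Participant]
    effect: EffectSpec
    seed: int

    def __post_init__(self) -> None:
        for p in self.participants:
            if sorted(p.sessions) != sorted(CONDITIONS):
                raise ParameterError(
                    f"participant {p.id} must have exactly one session per condition"
                )


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _session_trajectory(
    cond: str,
    effect: EffectSpec,
    tolerance: float,
    rng: np.random.Generator,
) -> AutonomicTrajectory:
    """Draw rating latencies and section layout for one session."""
    lat_table = effect.rating_latency_min[cond]
    shift = effect.tolerance_latency_min_per_sd * tolerance
    lats = []
    for rating in (1, 2, 3):
        mean, sd = lat_table[rating]
        # moderate/strong latencies are truncated at 5.5 min: the epoching
        # protocol needs the 5-min pre-rating window inside the section
        lo = 0.5 if rating == 1 else 5.5
        lats.append(_truncnorm(rng, mean + shift, sd, lo, 40.0) * 60.0)
    lats = np.maximum.accumulate(lats)  # ratings non-decreasing in time
    nausea_dur = 1200.0
    premature = None
    reached = [lat for lat in lats if lat < nausea_dur]
    if len(reached) == 3 and rng.uniform() < effect.premature_stop_prob[cond]:
        stop = min(lats[2] + rng.uniform(30.0, 120.0), 1200.0)
        if stop < 1200.0:
            nausea_dur = stop
            premature = 300.0 + stop
    ratings = tuple(
        (300.0 + lat, r + 1)
        for r, lat in enumerate(lats)
        if lat < nausea_dur - 1e-9
    )
    mods = {s: effect.modulation[(s, cond)] for s in SECTION_NAMES}
    sections = (
        ("baseline", 0.0) + mods["baseline"],
        ("nausea", 300.0) + mods["nausea"],
        ("recovery", 300.0 + nausea_dur) + mods["recovery"],
    )
    return AutonomicTrajectory(
        sections=sections,
        nausea_duration=nausea_dur,
        rating_events=ratings,
        premature_stop=premature,
    )


def _amplitude_envelopes(
    traj: AutonomicTrajectory, amp_factor: float
) -> tuple[np.ndarray, np.ndarray]:
    n = int(np.round(traj.total_duration * _IPFM_GRID_FS))
    t = np.arange(n) / _IPFM_GRID_FS
    a_lf = np.empty(n)
    a_hf = np.empty(n)
    bounds = [s[1] for s in traj.sections] + [traj.total_duration]
    for (name, start, alf, ahf), end in zip(traj.sections, bounds[1:]):
        seg = (t >= start) & (t < end)
        a_lf[seg] = alf * amp_factor
        a_hf[seg] = ahf * amp_factor
    return a_lf, a_hf


def _msaq_items(
    rng: np.random.Generator, base: np.ndarray, shift: float
) -> tuple[np.ndarray, np.ndarray]:
    """(pre, post) item scores from the latent-normal ordinal model."""
    pre_latent = base + rng.normal(0.0, 0.8, size=16)
    post_latent = base + shift + rng.normal(0.0, 0.8, size=16)
    to_item = lambda x: np.clip(np.round(x), 1, 9).astype(int)
    return to_item(pre_latent), to_item(post_latent)


def simulate_study(
    n_participants: int = 14,
    effect: EffectSpec | None = None,
    seed: int = 0,
) -> StudyDataset:
    """Simulate a full two-condition crossover cohort.

    Per participant, each condition yields a 5 min baseline + <=20 min
    nauseogenic + 5 min recovery session driven by an
    :class:`AutonomicTrajectory`; the nauseogenic section shifts HF
    modulation down / LF up relative to baseline, attenuated under tES per
    ``effect``.  Rating latencies are longer under tES; MSAQ responses get a
    condition-dependent latent shift.  Condition order is randomized and
    balanced as far as ``n_participants`` allows.
    """
    if n_participants < 2:
        raise ParameterError("need at least 2 participants")
    effect = effect or EffectSpec()
    effect.validate()
    rng = np.random.default_rng(seed)
    orders = np.array(
        [ORDERS[i % 2] for i in range(n_participants)], dtype=object
    )
    rng.shuffle(orders)
    participants = []
    for i in range(n_participants):
        pid = f"P{i+1:02d}"
        prng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        tolerance = prng.standard_normal()
        mean_rr = float(np.clip(prng.normal(effect.mean_rr, effect.participant_rr_sd),
                                0.6, 1.2))
        amp_factor = float(np.exp(
            prng.normal(0.0, effect.participant_amp_log_sd)
            + effect.tolerance_hf_log_gain * tolerance
        ))
        f_hf = float(np.clip(prng.normal(effect.f_hf, effect.participant_f_hf_sd),
                             0.18, 0.35))
        f_lf = float(np.clip(prng.normal(effect.f_lf, 0.008), 0.06, 0.14))
        sessions: dict[str, SessionRecording] = {}
        msaq: dict[str, dict[str, MSAQResponse]] = {}
        msaq_base = 1.5 + 0.5 * prng.standard_normal()
        for cond in CONDITIONS:
            srng = np.random.default_rng(prng.integers(0, 2**31 - 1))
            traj = _session_trajectory(cond, effect, tolerance, srng)
            a_lf_env, a_hf_env = _amplitude_envelopes(traj, amp_factor)
            rr = _ipfm_session(
                mean_rr,
                traj.total_duration,
                a_lf_env,
                a_hf_env,
                f_lf,
                f_hf,
                effect.broadband_sd,
                srng,
            )
            sess_seed = int(srng.integers(0, 2**31 - 1))
            sessions[cond] = SessionRecording(
                participant=pid, condition=cond, trajectory=traj, rr=rr,
                seed=sess_seed,
            )
            base_items = msaq_base + prng.normal(0.0, 0.4, size=16)
            pre, post = _msaq_items(srng, base_items, effect.msaq_shift[cond])
            msaq[cond] = {
                "pre": MSAQResponse(pre, "pre", pid, cond),
                "post": MSAQResponse(post, "post", pid, cond),
            }
        participants.append(
            Participant(id=pid, order=str(orders[i]), sessions=sessions, msaq=msaq)
        )
    return StudyDataset(participants=participants, effect=effect, seed=seed)


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------

def write_ecg_csv(ecg: ECGRecord, path: str | Path) -> None:
    """Two-column CSV: time_s, uV."""
    arr = np.column_stack([ecg.times, ecg.samples])
    np.savetxt(path, arr, delimiter=",", header="time_s,uv", comments="",
               fmt="%.6f")


def write_session(
    sess: SessionRecording,
    outdir: str | Path,
    fs: float = 256.0,
    noise_sd: float = 10.0,
    ecg_format: str = "edf",
) -> dict:
    """Write one session's ECG + events to disk; return a manifest entry."""
    from .edfio import write_edf  # local import: writer is optional plumbing

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"{sess.participant}_{sess.condition}"
    ecg = sess.ecg(fs=fs, noise_sd=noise_sd)
    if ecg_format == "csv":
        ecg_path = outdir / f"{stem}_ecg.csv"
        write_ecg_csv(ecg, ecg_path)
    elif ecg_format in ("edf", "bdf"):
        ecg_path = outdir / f"{stem}_ecg.{ecg_format}"
        write_edf(ecg_path, ecg.samples, fs, kind=ecg_format)
    else:
        raise ParameterError(f"unknown ECG format {ecg_format!r}")
    events_path = outdir / f"{stem}_events.json"
    events_to_json(sess.events, events_path)
    rr_path = outdir / f"{stem}_rr.csv"
    rr_to_csv(sess.rr, rr_path)
    return {
        "participant": sess.participant,
        "condition": sess.condition,
        "ecg": ecg_path.name,
        "events": events_path.name,
        "rr_ground_truth": rr_path.name,
    }


def write_msaq_csv(dataset: StudyDataset, path: str | Path) -> None:
    """MSAQ long table: participant, condition, timing, item01..item16."""
    lines = ["participant,condition,timing," +
             ",".join(f"item{i+1:02d}" for i in range(16))]
    for p in dataset.participants:
        for cond in CONDITIONS:
            for timing in ("pre", "post"):
                resp = p.msaq[cond][timing]
                lines.append(
                    f"{p.id},{cond},{timing},"
                    + ",".join(str(int(v)) for v in resp.item_scores)
                )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
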