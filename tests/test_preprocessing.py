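"""ECG ingest, zero-phase filtering, Pan-Tompkins detection, RR cleaning and
epoch extraction."""

import warnings

import numpy as np
import pytest
from scipy import signal as sps

from conftest import match_fraction
from vims_hrv.edfio import write_edf
from vims_hrv.errors import (
    FormatError,
    InsufficientDataError,
    ParameterError,
    TruncationError,
)
from vims_hrv.preprocessing import (
    bandpass_zero_phase,
    build_rr_series,
    detect_r_peaks,
    extract_epoch,
    read_ecg,
)
from vims_hrv.records import (
    PREMATURE_STOP,
    RATING,
    SECTION_START,
    BeatAnnotations,
    ECGRecord,
    Event,
    RRSeries,
)
from vims_hrv.synthetic import IPFMParams, noise_sd_for_snr, simulate_rr_ipfm, \
    synthesize_ecg, write_ecg_csv


class TestReadECG:
    def test_csv_duration_arithmetic(self, tmp_path):
        t = np.arange(256 * 10) / 256.0
        arr = np.column_stack([t, np.zeros_like(t)])
        path = tmp_path / "flat.csv"
        np.savetxt(path, arr, delimiter=",", header="time_s,uv", comments="")
        rec = read_ecg(path)
        assert rec.duration == pytest.approx(10.0)
        assert rec.fs == pytest.approx(256.0)

    @pytest.mark.parametrize("kind", ["edf", "bdf"])
    def test_edf_bdf_round_trip_within_quantization(self, tmp_path, kind):
        rr = simulate_rr_ipfm(IPFMParams(duration=20, seed=3))
        ecg = synthesize_ecg(rr, fs=256.0, noise_sd=5.0, seed=1)
        path = tmp_path / f"ecg.{kind}"
        write_edf(path, ecg.samples, 256.0, kind=kind)
        back = read_ecg(path)
        assert back.fs == pytest.approx(256.0)
        n = ecg.n_samples
        # 16-bit (EDF) quantization over the +-1 mV range is < 0.1 uV
        assert np.max(np.abs(back.samples[:n] - ecg.samples)) < 0.5

    def test_unknown_format_raises(self, tmp_path):
        p = tmp_path / "x.dat"
        p.write_text("nonsense")
        with pytest.raises(FormatError, match="unknown ECG format"):
            read_ecg(p)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FormatError):
            read_ecg(tmp_path / "absent.csv")

    def test_events_sidecar_loaded(self, tmp_path):
        from vims_hrv.records import events_to_json

        rr = simulate_rr_ipfm(IPFMParams(duration=20, seed=3))
        ecg = synthesize_ecg(rr, fs=256.0)
        path = tmp_path / "P01_sham_ecg.csv"
        write_ecg_csv(ecg, path)
        events_to_json([Event(0.0, SECTION_START, "baseline")],
                       tmp_path / "P01_sham_events.json")
        rec = read_ecg(path)
        assert rec.events and rec.events[0].value == "baseline"


class TestBandpass:
    def _pulse(self, fs=256.0, at=5.0, dur=10.0):
        n = int(dur * fs)
        x = np.zeros(n)
        t = np.arange(n) / fs
        x += 1000 * np.exp(-0.5 * ((t - at) / 0.012) ** 2)
        return ECGRecord(samples=x, fs=fs)

    def test_zero_phase_keeps_pulse_position(self):
        rec = self._pulse()
        out = bandpass_zero_phase(rec, 5.0, 15.0)
        assert abs(int(np.argmax(out.samples)) - int(5.0 * 256)) <= 1

    def test_dc_offset_removed(self):
        rec = ECGRecord(samples=np.full(2560, 500.0), fs=256.0)
        out = bandpass_zero_phase(rec, 5.0, 15.0)
        assert abs(out.samples.mean()) < 1e-6 * 500

    def test_mains_tone_attenuated_20db(self):
        fs = 256.0
        t = np.arange(int(30 * fs)) / fs
        tone = 100 * np.sin(2 * np.pi * 50.0 * t)
        out = bandpass_zero_phase(ECGRecord(samples=tone, fs=fs), 5.0, 15.0)
        p_in = np.mean(tone**2)
        p_out = np.mean(out.samples**2)
        assert 10 * np.log10(p_in / p_out) >= 20.0

    def test_invalid_band_raises(self):
        rec = self._pulse()
        with pytest.raises(ParameterError):
            bandpass_zero_phase(rec, 20.0, 10.0)
        with pytest.raises(ParameterError):
            bandpass_zero_phase(rec, 5.0, 200.0)


class TestPanTompkins:
    def test_all_zero_signal_yields_no_peaks(self):
        rec = ECGRecord(samples=np.zeros(256 * 20), fs=256.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beats = detect_r_peaks(rec)
        assert len(beats) == 0

    def test_short_record_rejected(self):
        rec = ECGRecord(samples=np.zeros(256 * 5), fs=256.0)
        with pytest.raises(InsufficientDataError):
            detect_r_peaks(rec)

    def test_clean_60bpm_minute(self, clean_ecg_60s):
        beats = detect_r_peaks(clean_ecg_60s)
        truth = clean_ecg_60s.r_peak_times
        assert abs(len(beats) - len(truth)) <= 1
        interior = truth[(truth > 0.5) & (truth < clean_ecg_60s.duration - 0.5)]
        assert match_fraction(beats.r_peak_times, interior) == 1.0

    def test_refractory_period_respected(self):
        rr = simulate_rr_ipfm(IPFMParams(duration=120, seed=5))
        sd = noise_sd_for_snr(rr, 256.0, 10.0)
        ecg = synthesize_ecg(rr, fs=256.0, noise_sd=sd, seed=2)
        beats = detect_r_peaks(ecg)
        assert np.all(np.diff(beats.r_peak_times) >= 0.2 - 1e-9)

    def test_agrees_with_independent_prominence_detector(self):
        """On 20 random records the Pan-Tompkins count differs from a simple
        prominence-based reference detector by at most one beat."""
        for seed in range(20):
            rr = simulate_rr_ipfm(
                IPFMParams(mean_rr=0.7 + 0.03 * (seed % 5), duration=60,
                           seed=seed)
            )
            ecg = synthesize_ecg(rr, fs=256.0, noise_sd=10.0, seed=seed)
            beats = detect_r_peaks(ecg)
            # independent oracle: find_peaks on the bandpassed signal
            band = bandpass_zero_phase(ecg, 5.0, 15.0).samples
            ref, _ = sps.find_peaks(band, distance=int(0.3 * 256),
                                    prominence=0.5 * band.max())
            assert abs(len(beats) - len(ref)) <= 1


class TestRRSeries:
    def test_difference_arithmetic(self):
        beats = BeatAnnotations(np.array([0, 256, 512, 768]),
                                np.array([0.0, 1.0, 2.0, 3.0]))
        rr = build_rr_series(beats)
        np.testing.assert_allclose(rr.rr_ms, [1000.0, 1000.0, 1000.0])
        np.testing.assert_allclose(rr.beat_times, [1.0, 2.0, 3.0])
        assert not rr.quality_flags.any()

    def test_spurious_beat_flags_adjacent_intervals(self):
        times = np.arange(0.0, 30.0, 1.0)
        times = np.sort(np.append(times, 15.4))  # extra beat mid-record
        beats = BeatAnnotations((times * 256).astype(int), times)
        rr = build_rr_series(beats)
        flagged = rr.beat_times[rr.quality_flags]
        assert 15.4 in flagged and 16.0 in flagged
        assert rr.quality_flags.sum() == 2

    def test_clean_five_minutes_unflagged(self, clean_rr_300s):
        times = np.concatenate([[0.0], clean_rr_300s.beat_times])
        beats = BeatAnnotations((times * 256).astype(int), times)
        rr = build_rr_series(beats)
        assert rr.quality_flags.sum() == 0

    def test_single_beat_insufficient(self):
        beats = BeatAnnotations(np.array([0]), np.array([0.0]))
        with pytest.raises(InsufficientDataError):
            build_rr_series(beats)


def _session_rr(duration=1800.0):
    rr = simulate_rr_ipfm(IPFMParams(duration=duration, seed=9))
    return rr


def _events(nausea_dur, ratings=(), stop=None):
    evs = [
        Event(0.0, SECTION_START, "baseline"),
        Event(300.0, SECTION_START, "nausea"),
        Event(300.0 + nausea_dur, SECTION_START, "recovery"),
    ]
    evs += [Event(300.0 + t, RATING, v) for t, v in ratings]
    if stop is not None:
        evs.append(Event(300.0 + stop, PREMATURE_STOP, None))
    return evs


class TestEpochExtraction:
    def test_full_section_low_rating_uses_pre_recovery_window(self):
        rr = _session_rr()
        evs = _events(1200.0, ratings=[(360.0, 1)])
        _, window = extract_epoch(rr, evs, "nausea")
        assert window == (1200.0, 1500.0)  # [900, 1200] s after nausea onset

    def test_moderate_rating_anchors_window_before_trigger(self):
        rr = _session_rr()
        evs = _events(1200.0, ratings=[(400.0, 1), (800.0, 2)])
        _, window = extract_epoch(rr, evs, "nausea")
        assert window == (300.0 + 500.0, 300.0 + 800.0)

    def test_premature_stop_uses_pre_recovery_window(self):
        rr = _session_rr()
        evs = _events(750.0, ratings=[(400.0, 2), (700.0, 3)], stop=750.0)
        _, window = extract_epoch(rr, evs, "nausea")
        assert window == (300.0 + 450.0, 300.0 + 750.0)

    def test_max_rating_repeated_uses_first_trigger(self):
        rr = _session_rr()
        evs = _events(1200.0, ratings=[(600.0, 2), (900.0, 2)])
        _, window = extract_epoch(rr, evs, "nausea")
        assert window == (300.0 + 300.0, 300.0 + 600.0)

    def test_early_rating_raises_truncation_error(self):
        rr = _session_rr()
        evs = _events(1200.0, ratings=[(200.0, 2)])
        with pytest.raises(TruncationError, match="available"):
            extract_epoch(rr, evs, "nausea")

    def test_baseline_epoch(self):
        rr = _session_rr()
        evs = _events(1200.0)
        epoch, window = extract_epoch(rr, evs, "baseline")
        assert window == (0.0, 300.0)
        assert epoch.beat_times.min() >= 0.0
        assert epoch.beat_times.max() < 300.0

    def test_pure_function_of_events(self):
        rr = _session_rr()
        evs = _events(1100.0, ratings=[(500.0, 2)])
        w1 = extract_epoch(rr, evs, "nausea")[1]
        w2 = extract_epoch(rr, list(evs), "nausea")[1]
        assert w1 == w2
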