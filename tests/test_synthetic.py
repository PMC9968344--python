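"""Generator behavior: IPFM beat model, ECG synthesis, study-level cohorts."""

import numpy as np
import pytest

from vims_hrv.errors import ConfigurationError, ParameterError
from vims_hrv.records import RATING, SECTION_START, events_from_json, \
    events_to_json, rr_from_csv, rr_to_csv, section_bounds
from vims_hrv.spectral import lomb_scargle_psd, rr_band_powers
from vims_hrv.synthetic import (
    CONDITIONS,
    EffectSpec,
    IPFMParams,
    simulate_rr_ipfm,
    simulate_study,
    synthesize_ecg,
    write_msaq_csv,
)


class TestIPFM:
    def test_unmodulated_ipfm_is_a_metronome(self):
        rr = simulate_rr_ipfm(
            IPFMParams(mean_rr=1.0, a_lf=0, a_hf=0, broadband_sd=0, duration=60)
        )
        assert len(rr) == 60
        np.testing.assert_allclose(rr.rr_ms, 1000.0, atol=1e-6)
        np.testing.assert_allclose(rr.beat_times, np.arange(1, 61), atol=1e-9)

    def test_seeded_determinism(self):
        p = IPFMParams(duration=120.0, seed=42)
        a, b = simulate_rr_ipfm(p), simulate_rr_ipfm(p)
        assert a.rr_ms.tobytes() == b.rr_ms.tobytes()
        assert a.beat_times.tobytes() == b.beat_times.tobytes()

    def test_different_seed_differs(self):
        a = simulate_rr_ipfm(IPFMParams(duration=120.0, seed=1))
        b = simulate_rr_ipfm(IPFMParams(duration=120.0, seed=2))
        assert not np.array_equal(a.rr_ms, b.rr_ms)

    @pytest.mark.parametrize(
        "kwargs, fragment",
        [
            (dict(mean_rr=-1.0), "mean_rr"),
            (dict(a_lf=0.7), "a_lf"),
            (dict(a_hf=-0.1), "a_hf"),
            (dict(a_lf=0.5, a_hf=0.45, broadband_sd=0.1), "non-positive"),
            (dict(duration=1.0), "duration"),
        ],
    )
    def test_invalid_params_name_the_violated_invariant(self, kwargs, fragment):
        with pytest.raises(ParameterError, match=fragment):
            simulate_rr_ipfm(IPFMParams(**kwargs))

    def test_mean_rr_within_one_percent(self):
        rr = simulate_rr_ipfm(IPFMParams(duration=300.0, seed=3))
        assert abs(rr.rr_ms.mean() - 850.0) / 850.0 < 0.01

    def test_hf_modulation_recovered_spectrally(self):
        rr = simulate_rr_ipfm(
            IPFMParams(a_lf=0, a_hf=0.1, broadband_sd=0, duration=300, seed=1)
        )
        psd = lomb_scargle_psd(rr)
        assert abs(psd.freqs[np.argmax(psd.power)] - 0.25) <= 0.01

    @pytest.mark.parametrize("f_lf,f_hf", [(0.06, 0.20), (0.10, 0.25), (0.13, 0.35)])
    def test_planted_band_holds_the_larger_power_share(self, f_lf, f_hf):
        # plant one tone at a time; its band must dominate Total - VLF
        for a_lf, a_hf, band in ((0.08, 0.0, "lf"), (0.0, 0.08, "hf")):
            rr = simulate_rr_ipfm(
                IPFMParams(a_lf=a_lf, f_lf=f_lf, a_hf=a_hf, f_hf=f_hf,
                           broadband_sd=0.005, duration=300, seed=11)
            )
            bp = rr_band_powers(rr)
            if band == "lf":
                assert bp.lf_nu > bp.hf_nu
            else:
                assert bp.hf_nu > bp.lf_nu


class TestECGSynthesis:
    def test_noiseless_template_placement_on_sampling_grid(self):
        rr = simulate_rr_ipfm(
            IPFMParams(mean_rr=1.0, a_lf=0, a_hf=0, broadband_sd=0, duration=60)
        )
        ecg = synthesize_ecg(rr, fs=256.0, noise_sd=0.0)
        truth = ecg.r_peak_times
        np.testing.assert_allclose(truth, np.arange(0, 61), atol=1e-9)
        # R peaks dominate: the sample at each annotated beat is near 1000 uV
        idx = np.round(truth[1:-1] * 256).astype(int)
        assert np.all(ecg.samples[idx] > 900)

    def test_low_sampling_rate_rejected(self):
        rr = simulate_rr_ipfm(IPFMParams(duration=30))
        with pytest.raises(ParameterError, match="fs"):
            synthesize_ecg(rr, fs=64.0)

    def test_noise_is_seeded(self):
        rr = simulate_rr_ipfm(IPFMParams(duration=30, seed=1))
        a = synthesize_ecg(rr, noise_sd=20.0, seed=9)
        b = synthesize_ecg(rr, noise_sd=20.0, seed=9)
        assert a.samples.tobytes() == b.samples.tobytes()


class TestStudySimulation:
    def test_structure_and_session_timing(self):
        ds = simulate_study(14, seed=0)
        assert len(ds.participants) == 14
        orders = [p.order for p in ds.participants]
        assert sorted(set(orders)) == ["sham->tes", "tes->sham"]
        assert abs(orders.count("sham->tes") - orders.count("tes->sham")) <= 0
        for p in ds.participants:
            assert sorted(p.sessions) == sorted(CONDITIONS)
            for cond in CONDITIONS:
                traj = p.sessions[cond].trajectory
                bounds = section_bounds(traj.events())
                assert bounds["baseline"] == 0.0
                assert bounds["nausea"] == 300.0
                assert 300.0 < bounds["recovery"] <= 1500.0
                assert traj.nausea_duration <= 1200.0
                ratings = [e for e in traj.events() if e.kind == RATING]
                vals = [int(e.value) for e in sorted(ratings, key=lambda e: e.time_s)]
                assert vals == sorted(vals)

    def test_end_to_end_determinism(self):
        a = simulate_study(4, seed=5)
        b = simulate_study(4, seed=5)
        for pa, pb in zip(a.participants, b.participants):
            for cond in CONDITIONS:
                assert np.array_equal(pa.sessions[cond].rr.rr_ms,
                                      pb.sessions[cond].rr.rr_ms)
                assert np.array_equal(pa.msaq[cond]["post"].item_scores,
                                      pb.msaq[cond]["post"].item_scores)

    def test_missing_effect_cell_raises(self):
        bad = EffectSpec(modulation={("baseline", "sham"): (0.04, 0.08)})
        with pytest.raises(ConfigurationError, match="missing modulation cell"):
            simulate_study(4, bad, seed=0)

    def test_too_few_participants(self):
        with pytest.raises(ParameterError):
            simulate_study(1, seed=0)

    def test_tes_latencies_longer_on_average(self):
        # condition-specific latency tables: strong-nausea later under tES
        ds = simulate_study(40, seed=2)
        lats = {c: [] for c in CONDITIONS}
        for p in ds.participants:
            for c in CONDITIONS:
                for t, r in p.sessions[c].trajectory.rating_events:
                    if r == 3:
                        lats[c].append(t)
        assert np.mean(lats["tes"]) > np.mean(lats["sham"])

    def test_null_effect_keeps_paired_test_calibrated(self):
        """Zero-effect cohorts: the one-tailed HF n.u. paired test fires in
        at most 10% of replicate datasets at alpha = 0.05."""
        from vims_hrv.behavioral import paired_t_one_tailed
        from vims_hrv.pipeline import StudyConfig, _analyze_session, \
            _sessions_from_dataset

        cfg = StudyConfig(synthetic={"n_participants": 14}, analyze_from="rr",
                          run_tfr_stats=False)
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            ds = simulate_study(14, EffectSpec.null(), seed=50_000 + rep)
            hf_b, hf_n = [], []
            for pid, order, cond, rr, events, _ in _sessions_from_dataset(ds, cfg):
                if cond != "sham":
                    continue
                sa = _analyze_session(pid, cond, rr, events, cfg)
                hf_b.append(sa.band_powers["baseline"].hf_nu)
                hf_n.append(sa.band_powers["nausea"].hf_nu)
            res = paired_t_one_tailed(np.array(hf_b), np.array(hf_n), "greater")
            hits += res.p_value < 0.05
        assert hits <= 0.10 * n_rep


class TestWriters:
    def test_events_json_round_trip(self, tmp_path):
        ds = simulate_study(2, seed=1)
        evs = ds.participants[0].sessions["sham"].events
        path = tmp_path / "events.json"
        events_to_json(evs, path)
        back = events_from_json(path)
        assert [(e.time_s, e.kind, e.value) for e in back] == [
            (e.time_s, e.kind, e.value) for e in evs
        ]

    def test_rr_csv_round_trip(self, tmp_path):
        rr = simulate_rr_ipfm(IPFMParams(duration=60, seed=1))
        path = tmp_path / "rr.csv"
        rr_to_csv(rr, path)
        back = rr_from_csv(path)
        np.testing.assert_allclose(back.rr_ms, rr.rr_ms, atol=1e-3)

    def test_msaq_csv_shape(self, tmp_path):
        ds = simulate_study(3, seed=1)
        path = tmp_path / "msaq.csv"
        write_msaq_csv(ds, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + 3 * 2 * 2  # header + participants x cond x timing
        assert lines[0].startswith("participant,condition,timing,item01")
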