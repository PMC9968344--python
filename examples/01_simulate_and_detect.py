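"""Simulate a modulated heartbeat, render it as ECG, and detect the R-peaks.

The IPFM model integrates a rate modulated at 0.10 Hz (LF) and 0.25 Hz (HF)
to unit thresholds; each crossing is a beat.  The synthesized ECG places a
PQRST template at every beat and the Pan-Tompkins detector recovers them.
"""

import numpy as np

from vims_hrv import IPFMParams, detect_r_peaks, noise_sd_for_snr, \
    simulate_rr_ipfm, synthesize_ecg

rr = simulate_rr_ipfm(IPFMParams(mean_rr=0.85, a_lf=0.04, a_hf=0.08,
                                 broadband_sd=0.012, duration=120.0, seed=1))
print(f"simulated {len(rr)} RR intervals, mean {rr.rr_ms.mean():.1f} ms "
      f"(target 850 ms), SD {rr.rr_ms.std():.1f} ms")

noise_sd = noise_sd_for_snr(rr, fs=256.0, snr_db=10.0)
ecg = synthesize_ecg(rr, fs=256.0, noise_sd=noise_sd, seed=2)
beats = detect_r_peaks(ecg)

truth = ecg.r_peak_times
idx = np.clip(np.searchsorted(beats.r_peak_times, truth), 1,
              len(beats) - 1)
err = np.minimum(np.abs(truth - beats.r_peak_times[idx - 1]),
                 np.abs(truth - beats.r_peak_times[idx]))
print(f"detected {len(beats)} beats of {len(truth)} at 10 dB SNR; "
      f"{np.mean(err <= 0.020):.1%} matched within 20 ms")
# A detection rate near 100% means the RR series downstream is trustworthy.
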