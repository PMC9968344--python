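import numpy as np
import pytest

from vims_hrv.synthetic import IPFMParams, simulate_rr_ipfm, synthesize_ecg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_rr_300s():
    """A 300 s modulated RR series (LF + HF tones + broadband noise)."""
    return simulate_rr_ipfm(IPFMParams(duration=300.0, seed=7))


@pytest.fixture(scope="session")
def clean_ecg_60s():
    """Noiseless 60 bpm ECG, 60 s at 256 Hz, with ground-truth peaks."""
    rr = simulate_rr_ipfm(
        IPFMParams(mean_rr=1.0, a_lf=0.0, a_hf=0.0, broadband_sd=0.0,
                   duration=61.0)
    )
    return synthesize_ecg(rr, fs=256.0, noise_sd=0.0)


def match_fraction(detected: np.ndarray, truth: np.ndarray,
                   tol_s: float = 0.020) -> float:
    """Fraction of `truth` times with a detection within `tol_s`."""
    if truth.size == 0:
        return 1.0
    if detected.size == 0:
        return 0.0
    idx = np.searchsorted(detected, truth)
    idx = np.clip(idx, 1, detected.size - 1)
    nearest = np.minimum(
        np.abs(truth - detected[idx - 1]), np.abs(truth - detected[idx])
    )
    return float(np.mean(nearest <= tol_s))
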