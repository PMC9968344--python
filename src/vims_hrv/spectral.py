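"""Lomb-Scargle spectral HRV: PSD on the irregular tachogram and band powers.

The periodogram is computed directly on the unevenly sampled RR series
(flagged intervals omitted -- the estimator tolerates gaps, which is exactly
its advantage here) and rescaled so that the integral of the PSD over the
analysis range equals the series variance; band integrals are then variance
contributions in ms^2.  Normalized units follow the standard definitions::

    LF n.u. = LF / (Total - VLF) * 100
    HF n.u. = HF / (Total - VLF) * 100
    ln LF/HF = log(LF / HF)

with VLF <= 0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.40 Hz, Total <= 0.40 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import InsufficientDataError, ParameterError
from .records import RRSeries

VLF_EDGE = 0.04
LF_EDGE = 0.15
HF_EDGE = 0.40


@dataclass
class PSDEstimate:
    """One-sided PSD of the tachogram in ms^2/Hz on a monotone grid."""

    freqs: np.ndarray
    power: np.ndarray
    method: str = "lomb-scargle"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ParameterError("freqs and power must have the same shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ParameterError("frequency grid must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ParameterError("power must be non-negative")
        self.power = np.clip(self.power, 0.0, None)


@dataclass
class BandPowers:
    """Absolute band powers (ms^2), normalized units (%) and ln(LF/HF)."""

    vlf_ms2: float
    lf_ms2: float
    hf_ms2: float
    total_ms2: float
    lf_nu: float
    hf_nu: float
    ln_lf_hf: float
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "vlf_ms2": self.vlf_ms2,
            "lf_ms2": self.lf_ms2,
            "hf_ms2": self.hf_ms2,
            "total_ms2": self.total_ms2,
            "lf_nu": self.lf_nu,
            "hf_nu": self.hf_nu,
            "ln_lf_hf": self.ln_lf_hf,
        }


def lomb_scargle_psd(
    rr: RRSeries,
    f_max: float = HF_EDGE,
    oversample: int = 4,
    min_intervals: int = 30,
    provenance: dict | None = None,
) -> PSDEstimate:
    """Lomb-Scargle periodogram of the mean-centred RR series.

    The grid runs from 1/duration to ``f_max`` with spacing
    ``1/(oversample * duration)``; the raw periodogram is rescaled so the
    trapezoidal integral over the grid equals the variance of the retained
    intervals (Parseval-style band normalization).
    """
    t, y = rr.clean
    if t.size < min_intervals:
        raise InsufficientDataError(
            f"only {t.size} unflagged intervals; need >= {min_intervals}"
        )
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise InsufficientDataError("zero time span")
    y = y - y.mean()
    var = float(np.var(y))
    f0 = 1.0 / duration
    df = f0 / oversample
    freqs = np.arange(f0, f_max + df / 2, df)
    if freqs[-1] < f_max:   # make sure the HF edge itself is on the grid
        freqs = np.append(freqs, f_max)
    raw = signal.lombscargle(t, y, 2 * np.pi * freqs)
    area = float(np.trapezoid(raw, freqs))
    scale = var / area if area > 0 else 0.0
    return PSDEstimate(
        freqs=freqs,
        power=raw * scale,
        provenance=dict(provenance or {}, duration_s=duration, n_intervals=int(t.size)),
    )


def _band_integral(freqs: np.ndarray, power: np.ndarray,
                   lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi], interpolating the edges."""
    lo = max(lo, float(freqs[0]))
    hi = min(hi, float(freqs[-1]))
    if hi <= lo:
        return 0.0
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    vals = np.interp(grid, freqs, power)
    return float(np.trapezoid(vals, grid))


def band_metrics(
    vlf_ms2: float, lf_ms2: float, hf_ms2: float, provenance: dict | None = None
) -> BandPowers:
    """Normalized-unit metrics from absolute band powers.

    ``lf_nu + hf_nu == 100`` holds identically because Total = VLF + LF + HF
    partitions the analysis range.
    """
    for name, v in (("vlf", vlf_ms2), ("lf", lf_ms2), ("hf", hf_ms2)):
        if v < 0:
            raise ParameterError(f"{name} power must be non-negative")
    if hf_ms2 == 0:
        raise ParameterError("HF power is zero: LF/HF ratio undefined")
    total = vlf_ms2 + lf_ms2 + hf_ms2
    # Total - VLF = LF + HF identically; the direct sum avoids cancellation
    denom = lf_ms2 + hf_ms2
    if denom <= 0:
        raise ParameterError("Total - VLF power must be positive")
    return BandPowers(
        vlf_ms2=vlf_ms2,
        lf_ms2=lf_ms2,
        hf_ms2=hf_ms2,
        total_ms2=total,
        lf_nu=lf_ms2 / denom * 100.0,
        hf_nu=hf_ms2 / denom * 100.0,
        ln_lf_hf=float(np.log(lf_ms2 / hf_ms2)),
        provenance=dict(provenance or {}),
    )


def compute_hrv_metrics(
    psd: PSDEstimate,
    vlf_edge: float = VLF_EDGE,
    lf_edge: float = LF_EDGE,
    hf_edge: float = HF_EDGE,
) -> BandPowers:
    """Band-integrate a PSD into VLF/LF/HF/Total powers and normalized units."""
    if not 0 < vlf_edge < lf_edge < hf_edge:
        raise ParameterError("band edges must satisfy 0 < VLF < LF < HF")
    if psd.freqs[-1] < hf_edge - 1e-9:
        raise ParameterError(
            f"PSD grid must reach {hf_edge} Hz; it ends at {psd.freqs[-1]:.3f} Hz"
        )
    vlf = _band_integral(psd.freqs, psd.power, 0.0, vlf_edge)
    lf = _band_integral(psd.freqs, psd.power, vlf_edge, lf_edge)
    hf = _band_integral(psd.freqs, psd.power, lf_edge, hf_edge)
    return band_metrics(vlf, lf, hf, provenance=dict(psd.provenance))


def rr_band_powers(rr: RRSeries, provenance: dict | None = None) -> BandPowers:
    """Convenience: Lomb-Scargle PSD + band metrics in one call."""
    return compute_hrv_metrics(lomb_scargle_psd(rr, provenance=provenance))
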