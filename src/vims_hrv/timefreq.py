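"""Time-frequency HRV: uniform resampling, analytic signal and the smoothed
pseudo Wigner-Ville distribution (SPWVD).

The SPWVD is the Cohen's-class distribution with separable smoothing,

    SPWVD(t, f) = sum_tau  h(tau) * [g *_t (z(t + tau/2) z*(t - tau/2))] e^{-j 2 pi f tau},

where ``g`` smooths along time (suppressing the time-oscillating cross-terms
of multicomponent signals) and the lag window ``h`` acts as frequency
smoothing.  The input is the analytic signal (Hilbert transform) of the
mean-centred, uniformly resampled tachogram.  The output is normalized so
that the integral over the full frequency axis at each time recovers the
(time-smoothed) instantaneous power ``|z(t)|^2``, giving ms^2/Hz units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import AlignmentError, InsufficientDataError, ParameterError
from .records import RRSeries

_WINDOW_SHAPES = ("hamming", "hann", "rect")


@dataclass
class UniformSeries:
    """Mean-centred, uniformly resampled tachogram (ms) at rate ``fs``."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ParameterError("fs must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


def resample_rr_uniform(
    rr: RRSeries,
    fs: float = 4.0,
    grid: tuple[float, int] | None = None,
) -> UniformSeries:
    """Cubic-spline interpolation of the RR series onto a uniform grid.

    With ``grid=(start, n)`` the output is forced onto that fixed grid
    (needed to align maps across sessions); samples outside the span of the
    beats are held at the edge values.  Otherwise the grid covers the beats'
    span only.  The output is mean-centred.
    """
    t, y = rr.clean
    if t.size < 4:
        raise InsufficientDataError("need >= 4 unflagged intervals for the spline")
    if t[-1] - t[0] < 4.0 / fs:
        raise InsufficientDataError("beat span too short for the requested rate")
    spline = CubicSpline(t, y)  # not-a-knot, the classic 'spline' interpolant
    if grid is None:
        t0 = float(np.ceil(t[0] * fs) / fs)
        n = int(np.floor((t[-1] - t0) * fs)) + 1
    else:
        t0, n = float(grid[0]), int(grid[1])
    tt = t0 + np.arange(n) / fs
    inside = np.clip(tt, t[0], t[-1])  # edge-hold outside the beat span
    vals = spline(inside)
    return UniformSeries(values=vals - vals.mean(), fs=fs, t0=t0)


@dataclass(frozen=True)
class SPWVDConfig:
    """Smoothing configuration of the SPWVD.

    ``time_window``/``freq_window`` are (shape, length-in-seconds) pairs;
    lengths are rounded to odd sample counts.  ``time_window=None`` disables
    time smoothing (pseudo-WVD); shape ``"rect"`` with ``freq_window`` gives
    an unsmoothed lag taper.  ``n_freq_bins`` frequency bins span
    (0, ``f_max``]; ``time_hop`` decimates the output time axis.
    """

    time_window: tuple[str, float] | None = ("hamming", 15.0)
    freq_window: tuple[str, float] = ("hamming", 31.0)
    n_freq_bins: int = 256
    f_max: float = 0.5
    time_hop: int = 1

    def validate(self, fs: float) -> None:
        if self.f_max > fs / 2 + 1e-12:
            raise ParameterError("f_max must not exceed the Nyquist frequency")
        if self.n_freq_bins < 8:
            raise ParameterError("n_freq_bins too small")
        if self.time_hop < 1:
            raise ParameterError("time_hop must be >= 1")
        for w in (self.time_window, self.freq_window):
            if w is not None and w[0] not in _WINDOW_SHAPES:
                raise ParameterError(f"unknown window shape {w[0]!r}")


def _odd_window(shape: str, length_s: float, fs: float) -> np.ndarray:
    n = max(1, int(round(length_s * fs)))
    if n % 2 == 0:
        n += 1
    if shape == "hamming":
        return np.hamming(n)
    if shape == "hann":
        return np.hanning(n)
    return np.ones(n)


@dataclass
class TFRMap:
    """Time x frequency power map (ms^2/Hz) with its smoothing provenance.

    ``edge_mask`` marks output columns inside the smoothing edge region
    (first/last window-half), which must be excluded from statistics.
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray  # shape (n_times, n_freqs)
    config: SPWVDConfig
    provenance: str = ""
    edge_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.times.size, self.freqs.size):
            raise ParameterError("power matrix does not match the axes")
        if not np.all(np.isfinite(self.power)):
            raise ParameterError("power matrix contains non-finite entries")
        if self.edge_mask is None:
            self.edge_mask = np.zeros(self.times.size, dtype=bool)
        else:
            self.edge_mask = np.asarray(self.edge_mask, dtype=bool)

    def crop_freq(self, lo: float, hi: float) -> "TFRMap":
        keep = (self.freqs >= lo - 1e-12) & (self.freqs <= hi + 1e-12)
        return replace(self, freqs=self.freqs[keep], power=self.power[:, keep])

    @property
    def interior(self) -> np.ndarray:
        return ~self.edge_mask


def spwvd(series: UniformSeries, config: SPWVDConfig | None = None,
          provenance: str = "") -> TFRMap:
    """Smoothed pseudo Wigner-Ville distribution of the analytic signal.

    Reflect-padding handles the time-convolution edges; columns within half
    of the combined window span of either end are flagged in ``edge_mask``.
    """
    config = config or SPWVDConfig()
    fs = series.fs
    config.validate(fs)
    x = series.values - series.values.mean()
    n = x.size
    g = (_odd_window(*config.time_window, fs) if config.time_window
         else np.ones(1))
    g = g / g.sum()
    h = _odd_window(*config.freq_window, fs)
    half_lag = (h.size - 1) // 2
    h_pos = h[half_lag:] / h[half_lag]  # h[0] = 1 normalization
    if n < max(g.size, h.size):
        raise ParameterError(
            f"series of {n} samples is shorter than the smoothing windows"
        )
    z = sps.hilbert(x)
    pad = half_lag + g.size // 2
    zp = np.pad(z, pad, mode="reflect")
    npad = zp.size
    # instantaneous autocorrelation K[m, n] = z[n+m] conj(z[n-m]), m >= 0
    K = np.zeros((half_lag + 1, npad), dtype=complex)
    K[0] = zp * np.conj(zp)
    for m in range(1, half_lag + 1):
        K[m, m:npad - m] = zp[2 * m:] * np.conj(zp[: npad - 2 * m])
    # time smoothing by g, then crop to the original support
    if g.size > 1:
        K = sps.fftconvolve(K, g[None, :], mode="same", axes=1)
    K = K[:, pad:pad + n]
    cols = np.arange(0, n, config.time_hop)
    K = K[:, cols] * h_pos[:, None]
    # FFT over the lag axis; f_k = k fs / (2 Nfft) since tau_m = 2m/fs
    nfft = int(round(config.n_freq_bins * fs / (2.0 * config.f_max)))
    if nfft < h_pos.size:
        raise ParameterError("n_freq_bins too small for the lag window length")
    A = np.zeros((nfft, K.shape[1]), dtype=complex)
    A[: half_lag + 1] = K
    A[nfft - half_lag:] = np.conj(K[1:][::-1])
    W = np.fft.fft(A, axis=0).real * (2.0 / fs)
    freqs = np.arange(nfft) * fs / (2.0 * nfft)
    keep = freqs <= config.f_max + 1e-12
    power = W[keep].T  # (n_times, n_freqs)
    edge = pad  # combined half-window span, in input samples
    edge_mask = (cols < edge) | (cols >= n - edge)
    return TFRMap(
        times=series.t0 + cols / fs,
        freqs=freqs[keep],
        power=power,
        config=config,
        provenance=provenance,
        edge_mask=edge_mask,
    )


def tfr_contrast(a: TFRMap, b: TFRMap) -> TFRMap:
    """Element-wise difference ``a - b`` ("X vs Y" means X - Y)."""
    if a.power.shape != b.power.shape or not (
        np.allclose(a.times, b.times) and np.allclose(a.freqs, b.freqs)
    ):
        raise AlignmentError("maps must share identical time/frequency axes")
    if a.config != b.config:
        raise AlignmentError("maps must share the same smoothing configuration")
    return TFRMap(
        times=a.times.copy(),
        freqs=a.freqs.copy(),
        power=a.power - b.power,
        config=a.config,
        provenance=f"({a.provenance})-({b.provenance})",
        edge_mask=a.edge_mask | b.edge_mask,
    )


def session_tfr(
    rr: RRSeries,
    window: tuple[float, float],
    config: SPWVDConfig | None = None,
    fs: float = 4.0,
    provenance: str = "",
) -> TFRMap:
    """Resample an epoch onto the fixed grid of ``window`` and run the SPWVD.

    All epochs of equal length produce maps with identical (relative) axes,
    as required for contrasts and permutation statistics.
    """
    start, end = window
    n = int(round((end - start) * fs))
    uni = resample_rr_uniform(rr, fs=fs, grid=(start, n))
    tfr = spwvd(UniformSeries(uni.values, fs, t0=0.0), config, provenance)
    return tfr
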