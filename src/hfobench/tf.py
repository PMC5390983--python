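"""Shared time-frequency machinery.

This module hosts the analytic-wavelet transform on a log-spaced frequency
grid, the Z_H0 background normalization (per-frequency Gaussian fit within
Tukey's range), the wavelet entropy of the autocorrelation used by the MNI
baseline stage, and the small spectral identities that explain why
line-length detection behaves like second-order differencing.

Two normalization conventions coexist on purpose:

* ``cwt_logscale`` uses *peak-normalized* kernels, so a unit sinusoid at a
  grid frequency has unit coefficient magnitude on every row.  Oscillations
  then have a comparable footprint at every frequency, which is what the
  oscillation/spike classification relies on.
* ``wavelet_entropy`` references each scale's power to the response the
  same kernel gives to band-limited white noise, so a featureless broadband
  window reaches the theoretical maximum entropy log10(|A|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sp_signal
from scipy.stats import norm as _norm

__all__ = [
    "TFMap",
    "ZH0Stats",
    "cwt_logscale",
    "zh0_normalize",
    "normalized_energy",
    "wavelet_entropy",
    "wavelet_entropy_max",
    "wavelet_entropy_profile",
    "second_diff_psd_factor",
    "sll_second_diff_equivalence",
    "welch_loglog_slope",
    "TUKEY_SD_CORRECTION",
]

# Inner Tukey fence for a Gaussian: Q3 + 1.5*IQR = (0.6745 + 1.5*1.349) sigma.
TUKEY_FENCE_SIGMA = 2.698

# SD of a Gaussian truncated to +/- k sigma, relative to the full SD:
# sqrt(1 - 2k phi(k) / (2 Phi(k) - 1)).  Dividing the sample SD of the
# retained coefficients by this factor recovers the untruncated SD.
TUKEY_SD_CORRECTION = float(
    np.sqrt(
        1.0
        - 2.0
        * TUKEY_FENCE_SIGMA
        * _norm.pdf(TUKEY_FENCE_SIGMA)
        / (2.0 * _norm.cdf(TUKEY_FENCE_SIGMA) - 1.0)
    )
)


@dataclass
class TFMap:
    """Complex time-frequency map, rows ordered by increasing frequency."""

    coefficients: np.ndarray  # complex, shape (n_freqs, n_samples)
    freqs_hz: np.ndarray
    fs: float
    wavelet: str = "morlet"
    omega0: float = 6.0
    enbw_hz: np.ndarray | None = None  # per-row equivalent noise bandwidth

    def __post_init__(self) -> None:
        if self.coefficients.shape[0] != len(self.freqs_hz):
            raise ValueError("row count must match frequency grid")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


@dataclass
class ZH0Stats:
    """Per-frequency Gaussian background fit of the real wavelet coefficients."""

    freqs_hz: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    enbw_hz: np.ndarray | None = None

    @property
    def background_power(self) -> np.ndarray:
        """Background power estimate per frequency (sigma squared)."""
        return self.sigma**2

    @property
    def background_psd(self) -> np.ndarray:
        """Background power spectral density estimate (arbitrary global scale).

        sigma^2 grows with the analysis kernel's bandwidth even for a flat
        spectrum; dividing by each row's equivalent noise bandwidth recovers
        the spectral *shape* of the background, comparable to the generating
        model's PSD up to one global offset.
        """
        if self.enbw_hz is None:
            raise ValueError("TF map carried no bandwidth information")
        return self.sigma**2 / self.enbw_hz


def log_freq_grid(f_min: float, f_max: float, voices_per_octave: int) -> np.ndarray:
    n_octaves = np.log2(f_max / f_min)
    n = int(np.floor(n_octaves * voices_per_octave)) + 1
    return f_min * 2.0 ** (np.arange(n) / voices_per_octave)


def _morlet_kernels(freqs: np.ndarray, fft_freqs: np.ndarray, omega0: float) -> np.ndarray:
    """Peak-normalized analytic Morlet kernels on the FFT grid.

    Each row is a Gaussian centred at the analysis frequency with spectral
    SD fa / omega0, zero at non-positive frequencies.  The factor 2 makes the
    response to a unit cosine at the centre frequency have unit magnitude.
    """
    fa = freqs[:, None]
    k = 2.0 * np.exp(-0.5 * (omega0 * (fft_freqs[None, :] - fa) / fa) ** 2)
    k[:, fft_freqs <= 0] = 0.0
    return k


def cwt_logscale(
    signal: np.ndarray,
    fs: float,
    f_min: float = 10.0,
    f_max: float = 512.0,
    voices_per_octave: int = 12,
    omega0: float = 6.0,
) -> TFMap:
    """Analytic Morlet wavelet transform on a log-spaced frequency grid.

    Kernels are peak-normalized so that a unit-amplitude sinusoid at any grid
    frequency produces coefficients of magnitude 1 on its row, independent of
    frequency.

    Parameters
    ----------
    signal : 1-D real array
    fs : sampling rate in Hz
    f_min, f_max : analysis band; ``f_max`` must stay below fs/2
    voices_per_octave : grid density (12 voices covers 80-500 Hz with ~32 rows)
    omega0 : Morlet time-bandwidth parameter (cycles within one time-SD ~ omega0/pi)
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    if f_max >= fs / 2:
        raise ValueError(f"f_max={f_max} must be below Nyquist ({fs / 2} Hz)")
    n = x.size
    # reflect-pad so the circular FFT convolution sees no amplitude jump at
    # the record ends (a zero-pad glitch would dominate the weakest rows)
    pad = min(n - 1, int(round(fs)))
    xp = np.concatenate([x[pad:0:-1], x, x[n - 2 : n - 2 - pad : -1]])
    nfft = sp_fft.next_fast_len(xp.size, real=False)
    freqs = log_freq_grid(f_min, f_max, voices_per_octave)
    fft_freqs = np.fft.fftfreq(nfft, d=1.0 / fs)
    spectrum = sp_fft.fft(xp, nfft)
    kernels = _morlet_kernels(freqs, fft_freqs, omega0)
    coeffs = np.empty((len(freqs), n), dtype=complex)
    for i in range(len(freqs)):
        coeffs[i] = sp_fft.ifft(spectrum * kernels[i])[pad : pad + n]
    df = fs / nfft
    enbw = (kernels**2).sum(axis=1) * df / (kernels.max(axis=1) ** 2)
    return TFMap(coefficients=coeffs, freqs_hz=freqs, fs=fs, omega0=omega0, enbw_hz=enbw)


def zh0_normalize(tf: TFMap) -> tuple[ZH0Stats, TFMap]:
    """Z-score each frequency row by a Gaussian fitted within Tukey's range.

    For every row the quartiles of the real coefficients define the Tukey
    range [Q1 - 1.5 IQR, Q3 + 1.5 IQR]; the mean and SD of the retained
    values, with the SD corrected for truncation, estimate the background
    distribution under the event-free null.  Real and imaginary parts are
    z-scored by the same SD, so event-free rows become standard normal.
    """
    coeffs = tf.coefficients
    if coeffs.shape[1] < 2 * tf.fs:
        raise ValueError("need at least 2 s of coefficients per row")
    re = coeffs.real
    q1, q3 = np.percentile(re, [25, 75], axis=1)
    iqr = q3 - q1
    bad = np.flatnonzero(iqr <= 0)
    if bad.size:
        raise ValueError(
            f"degenerate coefficient row at {tf.freqs_hz[bad[0]]:.1f} Hz (zero IQR)"
        )
    lo = (q1 - 1.5 * iqr)[:, None]
    hi = (q3 + 1.5 * iqr)[:, None]
    keep = (re >= lo) & (re <= hi)
    counts = keep.sum(axis=1)
    mu = np.where(keep, re, 0.0).sum(axis=1) / counts
    var = np.where(keep, (re - mu[:, None]) ** 2, 0.0).sum(axis=1) / counts
    sigma = np.sqrt(var) / TUKEY_SD_CORRECTION
    stats = ZH0Stats(freqs_hz=tf.freqs_hz, mu=mu, sigma=sigma, enbw_hz=tf.enbw_hz)
    z = (coeffs - mu[:, None]) / sigma[:, None]
    return stats, TFMap(
        coefficients=z,
        freqs_hz=tf.freqs_hz,
        fs=tf.fs,
        wavelet=tf.wavelet,
        omega0=tf.omega0,
        enbw_hz=tf.enbw_hz,
    )


def normalized_energy(ztf: TFMap) -> np.ndarray:
    """Normalized energy map (z_re^2 + z_im^2) / 2 of a z-scored TF map.

    Under the event-free null each pixel is ~ Exp(1), so a threshold of 30
    has a per-pixel tail probability of about 1e-13.
    """
    z = ztf.coefficients
    return 0.5 * (z.real**2 + z.imag**2)


# ---------------------------------------------------------------------------
# Wavelet entropy of the autocorrelation (MNI baseline criterion)
# ---------------------------------------------------------------------------

DEFAULT_WE_SCALES_HZ = (80.0, 160.0, 320.0)  # one per octave through the HFO band


def wavelet_entropy_max(n_scales: int) -> float:
    return float(np.log10(n_scales))


def _biased_autocorr(x: np.ndarray) -> np.ndarray:
    """Biased (divide by N) autocorrelation, full two-sided sequence."""
    n = x.size
    r = sp_signal.correlate(x, x, mode="full", method="fft") / n
    return r


def wavelet_entropy(
    window: np.ndarray,
    fs: float,
    scales_hz: tuple[float, ...] = DEFAULT_WE_SCALES_HZ,
    omega0: float = 6.0,
    band: tuple[float, float] = (80.0, 500.0),
) -> float:
    """Shannon-type entropy of normalized wavelet power of the autocorrelation.

    The window (already band-pass filtered to the HFO band) is reduced to its
    biased autocorrelation; Morlet kernels at the given scales are applied
    and the power distribution across scales, evaluated at zero lag, is fed
    to S = -sum P log10 P.  Each scale's power is referenced to the response
    the same kernel gives to band-limited white noise, so a featureless
    broadband window approaches the maximum log10(|A|) while a rhythmic
    window concentrates power at one scale and scores far lower.  S is
    invariant to amplitude scaling.
    """
    x = np.asarray(window, dtype=float)
    if x.size == 0 or not np.any(x):
        raise ValueError("wavelet entropy of an all-zero window is undefined")
    r = _biased_autocorr(x)
    p = _scale_powers_at_zero_lag(r, fs, tuple(scales_hz), omega0, band)
    p = p / p.sum()
    nz = p[p > 0]
    return float(-(nz * np.log10(nz)).sum())


def _scale_powers_at_zero_lag(
    r: np.ndarray,
    fs: float,
    scales_hz: tuple[float, ...],
    omega0: float,
    band: tuple[float, float] = (80.0, 500.0),
) -> np.ndarray:
    n = r.size
    center = n // 2
    nfft = sp_fft.next_fast_len(n, real=False)
    fft_freqs = np.fft.fftfreq(nfft, d=1.0 / fs)
    spectrum = sp_fft.fft(r, nfft)
    powers = np.empty(len(scales_hz))
    for i, fa in enumerate(scales_hz):
        k = np.exp(-0.5 * (omega0 * (fft_freqs - fa) / fa) ** 2)
        k[fft_freqs <= 0] = 0.0
        # white reference: a flat in-band spectrum must yield equal power at
        # every scale (the maximum-entropy baseline), so normalize by the
        # kernel's in-band area
        inband = k.copy()
        inband[(fft_freqs < band[0]) | (fft_freqs > band[1])] = 0.0
        k /= inband.sum()
        row = sp_fft.ifft(spectrum * k)
        powers[i] = np.abs(row[center]) ** 2
    return powers


def wavelet_entropy_profile(
    signal: np.ndarray,
    fs: float,
    window_s: float = 0.125,
    scales_hz: tuple[float, ...] = DEFAULT_WE_SCALES_HZ,
    omega0: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Wavelet entropy of consecutive windows of a band-passed signal.

    Returns (window start times in s, entropy per window).  All-zero windows
    get NaN instead of raising, so fully silenced stretches do not abort a
    whole-record scan.
    """
    x = np.asarray(signal, dtype=float)
    wlen = int(round(window_s * fs))
    n_win = x.size // wlen
    times = np.arange(n_win) * window_s
    entropies = np.full(n_win, np.nan)
    for i in range(n_win):
        seg = x[i * wlen : (i + 1) * wlen]
        if np.any(seg):
            entropies[i] = wavelet_entropy(seg, fs, scales_hz, omega0)
    return times, entropies


# ---------------------------------------------------------------------------
# Spectral identities behind line-length detection
# ---------------------------------------------------------------------------


def second_diff_psd_factor(omega):
    """Power gain of twice-applied first differencing at normalized frequency.

    Equals |1 - e^{-j w}|^4 = 2 (3 + cos 2w - 4 cos w); zero at DC, 16 at
    Nyquist, monotonically increasing in between -- the reason a line-length
    stage over-expresses the fast-ripple band relative to the ripple band.
    """
    w = np.asarray(omega, dtype=float)
    return 2.0 * (3.0 + np.cos(2.0 * w) - 4.0 * np.cos(w))


def sll_second_diff_equivalence(x: np.ndarray, window: int) -> float:
    """Max discrepancy between the line-length energy of the first-differenced
    signal and the windowed sum of |second difference|.

    The two are the same quantity written two ways; this computes both from
    independent code paths and returns their maximum absolute difference
    (expected to be numerically zero).
    """
    x = np.asarray(x, dtype=float)
    if x.size <= window + 2:
        raise ValueError("signal must be longer than the window")
    x1 = np.diff(x)
    # path 1: line length of x1 over a sliding window
    ll_terms = np.abs(np.diff(x1))
    e_ll = np.convolve(ll_terms, np.ones(window - 1), mode="valid")
    # path 2: windowed sum of |second difference of x|
    x2 = x[2:] - 2.0 * x[1:-1] + x[:-2]
    e_sd = np.convolve(np.abs(x2), np.ones(window - 1), mode="valid")
    return float(np.max(np.abs(e_ll - e_sd)))


def welch_loglog_slope(
    x: np.ndarray, fs: float, f_lo: float = 10.0, f_hi: float = 500.0, nperseg: int = 4096
) -> float:
    """Least-squares slope of log10 PSD vs log10 frequency over a band."""
    f, pxx = sp_signal.welch(np.asarray(x, dtype=float), fs=fs, nperseg=nperseg)
    sel = (f >= f_lo) & (f <= f_hi) & (pxx > 0)
    return float(np.polyfit(np.log10(f[sel]), np.log10(pxx[sel]), 1)[0])
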