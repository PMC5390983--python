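"""Delphos: oscillation/spike detection in the Z_H0-normalized time-frequency map.

The raw (unfiltered) signal is wavelet-transformed on a log frequency grid,
each frequency row is z-scored by a Gaussian fitted to the real coefficients
within Tukey's range, and local maxima of the normalized energy map above a
threshold (default 30) are characterized by their half-height time width and
frequency spread.  A peak whose frequency spread matches the wavelet's own
and whose time width exceeds that of a Dirac impulse is an oscillation; the
converse signature is a spike.  Reference widths are self-calibrated per
frequency from the transform's response to a synthetic impulse and tones.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .. import tf as hft
from .base import Detection, DetectorOutput, EDGE_EXCLUDE_S

__all__ = ["DelphosParams", "detect_delphos", "hfo_oscillations", "delphos_calibration"]


@dataclass
class DelphosParams:
    threshold: float = 30.0  # normalized energy
    f_min: float = 10.0
    # grid extends well above the 500 Hz scoring band: the background power
    # keeps falling with frequency, so the normalized upper tail of a fast
    # event needs ~2/3 octave of headroom before it drops below half height;
    # without it blobs near 450 Hz are clipped by the analysis edge
    f_max: float = 800.0
    voices_per_octave: int = 12
    omega0: float = 6.0
    # classification tolerances relative to the calibrated references
    fspread_factor: float = 1.5
    twidth_factor: float = 1.5
    hfo_band: tuple[float, float] = (80.0, 500.0)


@functools.lru_cache(maxsize=8)
def delphos_calibration(
    fs: float, f_min: float, f_max: float, voices_per_octave: int, omega0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frequency reference responses measured on calibration signals.

    Returns (freqs, tone_profiles, dirac_twidth): ``tone_profiles[:, a]`` is
    the energy column a pure tone at grid frequency ``a`` produces across
    rows, and ``dirac_twidth[a]`` the half-height time width (seconds) of a
    unit impulse on row ``a``.  At detection time the tone profiles are
    re-weighted by the record's per-row background power, so the reference
    frequency spread adapts to the background spectrum the same way the
    normalized map does.
    """
    n = int(round(2.0 * fs))
    freqs = hft.log_freq_grid(f_min, f_max, voices_per_octave)
    # impulse: time width per row (row shape is normalization-invariant)
    impulse = np.zeros(n)
    impulse[n // 2] = 1.0
    tfm = hft.cwt_logscale(impulse, fs, f_min, f_max, voices_per_octave, omega0)
    energy = np.abs(tfm.coefficients) ** 2
    twidth = np.empty(len(freqs))
    for i in range(len(freqs)):
        row = energy[i]
        above = row > row[n // 2] / 2.0
        twidth[i] = _extent_around(above, n // 2) / fs
    # tones: full cross-row energy profile at each grid frequency
    t = np.arange(n) / fs
    profiles = np.empty((len(freqs), len(freqs)))
    for i, f0 in enumerate(freqs):
        tone = np.cos(2 * np.pi * f0 * t)
        tfm = hft.cwt_logscale(tone, fs, f_min, f_max, voices_per_octave, omega0)
        profiles[:, i] = np.abs(tfm.coefficients[:, n // 2]) ** 2
    return freqs, profiles, twidth


def _spread_octaves(col: np.ndarray, a: int, voices_per_octave: int) -> float:
    """Half-height extent (octaves) of the run containing row ``a``; infinite
    when the run is clipped by the analysis band (narrowness not certifiable)."""
    above = col > col[a] / 2.0
    lo = a
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = a
    while hi < col.size - 1 and above[hi + 1]:
        hi += 1
    if lo == 0 or hi == col.size - 1:
        return float("inf")
    return (hi - lo + 1) / voices_per_octave


def _extent_around(mask: np.ndarray, idx: int) -> int:
    """Length of the contiguous True run containing ``idx``."""
    lo = idx
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = idx
    while hi < mask.size - 1 and mask[hi + 1]:
        hi += 1
    return hi - lo + 1


def detect_delphos(
    signal: np.ndarray, fs: float, params: DelphosParams | None = None
) -> DetectorOutput:
    params = params or DelphosParams()
    x = np.asarray(signal, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("Delphos needs at least 2 s of signal for normalization")
    tfm = hft.cwt_logscale(
        x, fs, params.f_min, params.f_max, params.voices_per_octave, params.omega0
    )
    stats, ztf = hft.zh0_normalize(tfm)
    energy = hft.normalized_energy(ztf)
    freqs, tone_profiles, cal_twidth = delphos_calibration(
        fs, params.f_min, params.f_max, params.voices_per_octave, params.omega0
    )
    # reference tone columns as they would appear in THIS record's
    # normalized map: calibration profile divided by the background power
    ref_cols = tone_profiles / stats.background_power[:, None]

    n = x.size
    e0 = int(round(EDGE_EXCLUDE_S * fs))
    # 2-D local maxima above threshold (neighborhood ~3 rows x 5 ms)
    foot_t = max(3, int(round(0.005 * fs)) | 1)
    local_max = ndimage.maximum_filter(energy, size=(3, foot_t), mode="nearest")
    cand = (energy >= local_max) & (energy > params.threshold)
    cand[:, :e0] = False
    cand[:, n - e0 :] = False
    rows, cols = np.nonzero(cand)
    order = np.argsort(energy[rows, cols])[::-1]

    step = 1.0 / params.voices_per_octave
    claimed: list[tuple[int, int, int, int]] = []  # (a0, a1, b0, b1) of accepted peaks
    detections: list[Detection] = []
    for idx in order:
        a, b = int(rows[idx]), int(cols[idx])
        if any(a0 <= a <= a1 and b0 <= b <= b1 for a0, a1, b0, b1 in claimed):
            continue
        peak = energy[a, b]
        half = peak / 2.0
        row = energy[a]
        b_lo = b
        while b_lo > 0 and row[b_lo - 1] > half:
            b_lo -= 1
        b_hi = b
        while b_hi < n - 1 and row[b_hi + 1] > half:
            b_hi += 1
        col = energy[:, b]
        above = col > col[a] / 2.0
        a_lo = a
        while a_lo > 0 and above[a_lo - 1]:
            a_lo -= 1
        a_hi = a
        while a_hi < len(freqs) - 1 and above[a_hi + 1]:
            a_hi += 1
        # suppress only nearby duplicate maxima of the same blob; a distinct
        # structure higher or lower in frequency (e.g. an oscillation under a
        # broadband transient ridge) must stay detectable
        claimed.append((max(a_lo, a - 4), min(a_hi, a + 4), b_lo, b_hi))

        twidth = (b_hi - b_lo + 1) / fs
        fspread = _spread_octaves(col, a, params.voices_per_octave)
        # physical peak frequency: the background normalization tilts blobs
        # up in frequency, so locate the maximum of the *raw* energy within
        # the blob's row run
        raw_col = np.abs(tfm.coefficients[a_lo : a_hi + 1, b]) ** 2
        a_peak = a_lo + int(np.argmax(raw_col))
        ref_fspread = _spread_octaves(ref_cols[:, a], a, params.voices_per_octave)
        narrow_f = np.isfinite(fspread) and fspread <= params.fspread_factor * ref_fspread
        long_t = twidth >= params.twidth_factor * cal_twidth[a]
        if narrow_f and long_t:
            dtype = "oscillation"
        elif (not narrow_f) and not long_t:
            dtype = "spike"
        else:
            dtype = "unspecified"
        detections.append(
            Detection(
                t_start_s=b_lo / fs,
                t_end_s=(b_hi + 1) / fs,
                t_peak_s=b / fs,
                detector="delphos",
                type=dtype,
                peak_freq_hz=float(freqs[a_peak]),
                score=float(peak),
            )
        )
    return DetectorOutput(detections, params.threshold, {"n_candidates": len(order)})


def hfo_oscillations(
    detections: list[Detection], band: tuple[float, float] = (80.0, 500.0)
) -> list[Detection]:
    """Oscillation-type detections whose peak frequency lies in the HFO band."""
    return [
        d
        for d in detections
        if d.type == "oscillation"
        and d.peak_freq_hz is not None
        and band[0] <= d.peak_freq_hz <= band[1]
    ]
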