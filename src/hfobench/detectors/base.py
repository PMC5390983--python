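"""Common detector plumbing: the Detection record, the 80-500 Hz zero-phase
front-end and small segment utilities shared by the time-domain detectors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

__all__ = ["Detection", "DetectorOutput", "bandpass_80_500", "EDGE_EXCLUDE_S"]

# first/last stretch excluded from detection (filter and CWT edge effects)
EDGE_EXCLUDE_S = 0.5


@dataclass
class Detection:
    """One detector output interval (half-open in time)."""

    t_start_s: float
    t_end_s: float
    t_peak_s: float
    detector: str
    type: str = "unspecified"  # oscillation | spike | unspecified
    peak_freq_hz: float | None = None
    score: float = float("nan")

    def __post_init__(self) -> None:
        if not self.t_start_s < self.t_end_s:
            raise ValueError("detection interval must have positive length")


@dataclass
class DetectorOutput:
    """Detections plus the per-record threshold diagnostic."""

    detections: list[Detection]
    threshold: float
    extras: dict = field(default_factory=dict)


_FIR_CACHE: dict[tuple, np.ndarray] = {}


def _design_bandpass(fs: float) -> np.ndarray:
    key = (fs,)
    if key not in _FIR_CACHE:
        width = min(20.0, (fs / 2.0 - 500.0) * 0.9)
        numtaps, beta = sp_signal.kaiserord(60.0, width / (fs / 2.0))
        numtaps |= 1  # odd length, linear phase type I
        _FIR_CACHE[key] = sp_signal.firwin(
            numtaps, [80.0, 500.0], window=("kaiser", beta), pass_zero=False, fs=fs
        )
    return _FIR_CACHE[key]


def bandpass_80_500(signal: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase FIR band-pass 80-500 Hz (>= 60 dB stopband, length preserved)."""
    if fs <= 1010.0:
        raise ValueError(f"fs={fs} Hz too low for a 500 Hz passband edge")
    x = np.asarray(signal, dtype=float)
    taps = _design_bandpass(fs)
    return sp_signal.filtfilt(taps, [1.0], x, padlen=min(3 * taps.size, x.size - 1))


def runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i0, i1) index runs where the boolean mask is True."""
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return list(zip(starts.tolist(), ends.tolist()))


def merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Merge runs separated by fewer than ``max_gap`` samples."""
    if not runs:
        return []
    merged = [runs[0]]
    for i0, i1 in runs[1:]:
        if i0 - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))
    return merged


def edge_mask(n: int, fs: float, exclude_s: float = EDGE_EXCLUDE_S) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    e = int(round(exclude_s * fs))
    m[e : n - e] = True
    return m


def moving_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving RMS, same length as the input."""
    from scipy.ndimage import uniform_filter1d

    return np.sqrt(np.maximum(uniform_filter1d(x * x, size=window, mode="nearest"), 0.0))
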