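"""Short Line Length (SLL) detector.

The raw signal is first-order backward differenced, band-pass filtered, and
the line-length energy (sum of absolute successive differences) over a 12 ms
sliding window is thresholded at the 97.5th percentile of its empirical
distribution; supra-threshold stretches of at least 12 ms are detections.

Because line length of a differenced signal equals a rectified moving
average of the *second* difference, this detector implicitly applies a
|1 - e^{-jw}|^4 spectral weighting that over-expresses the fast-ripple band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import Detection, DetectorOutput, bandpass_80_500, edge_mask, runs_above

__all__ = ["SLLParams", "detect_sll", "line_length_energy"]


@dataclass
class SLLParams:
    window_s: float = 0.012
    min_duration_s: float = 0.012
    percentile: float = 97.5


def line_length_energy(x: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window sum of |successive differences|, right-aligned, padded
    to the input length."""
    terms = np.abs(np.diff(x))
    if window - 1 > terms.size:
        raise ValueError("window longer than the signal")
    e = np.convolve(terms, np.ones(window - 1), mode="valid")
    # first full window ends at sample index window-1
    return np.r_[np.full(x.size - e.size, e[0]), e]


def detect_sll(
    signal: np.ndarray, fs: float, params: SLLParams | None = None
) -> DetectorOutput:
    params = params or SLLParams()
    x = np.asarray(signal, dtype=float)
    x1 = np.diff(x, prepend=x[0])  # first-order backward differencing
    bp = bandpass_80_500(x1, fs)
    window = max(2, int(round(params.window_s * fs)))
    energy = line_length_energy(bp, window)
    valid = edge_mask(x.size, fs)
    thr = float(np.percentile(energy[valid], params.percentile))
    min_len = int(round(params.min_duration_s * fs))
    detections = []
    for i0, i1 in runs_above((energy > thr) & valid):
        if i1 - i0 < min_len:
            continue
        ipeak = i0 + int(np.argmax(energy[i0:i1]))
        detections.append(
            Detection(
                t_start_s=i0 / fs,
                t_end_s=i1 / fs,
                t_peak_s=ipeak / fs,
                detector="sll",
                type="oscillation",
                score=float(energy[ipeak]),
            )
        )
    return DetectorOutput(detections, thr, {})
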