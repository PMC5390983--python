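"""Short Time Energy (STE) detector.

Moving RMS of the band-passed signal; segments above mean + 5 SD of the RMS
trace lasting at least 6 ms become candidates (after merging candidates
closer than 10 ms); a candidate is kept only if it contains more than 6
rectified-signal peaks above mean + 3 SD of the rectified trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelextrema

from .base import (
    Detection,
    DetectorOutput,
    bandpass_80_500,
    edge_mask,
    merge_runs,
    moving_rms,
    runs_above,
)

__all__ = ["STEParams", "detect_ste"]


@dataclass
class STEParams:
    # RIPPLELAB defaults for the RMS route
    rms_window_s: float = 0.003
    min_duration_s: float = 0.006  # 3 periods of a 500 Hz oscillation
    merge_gap_s: float = 0.010
    threshold_sd: float = 5.0
    peak_threshold_sd: float = 3.0
    min_peaks: int = 6  # strictly more than this many rectified peaks required


def detect_ste(
    signal: np.ndarray,
    fs: float,
    params: STEParams | None = None,
    prefiltered: bool = False,
) -> DetectorOutput:
    params = params or STEParams()
    x = np.asarray(signal, dtype=float)
    bp = x if prefiltered else bandpass_80_500(x, fs)
    rms = moving_rms(bp, max(1, int(round(params.rms_window_s * fs))))
    valid = edge_mask(x.size, fs)
    thr = float(rms[valid].mean() + params.threshold_sd * rms[valid].std())
    rect = np.abs(bp)
    rect_thr = float(rect[valid].mean() + params.peak_threshold_sd * rect[valid].std())

    candidates = merge_runs(
        runs_above((rms > thr) & valid), int(round(params.merge_gap_s * fs))
    )
    min_len = int(round(params.min_duration_s * fs))
    detections = []
    for i0, i1 in candidates:
        if i1 - i0 < min_len:
            continue
        seg = rect[i0:i1]
        peaks = argrelextrema(seg, np.greater)[0]
        n_peaks = int(np.sum(seg[peaks] > rect_thr))
        if n_peaks <= params.min_peaks:
            continue
        ipeak = i0 + int(np.argmax(rms[i0:i1]))
        detections.append(
            Detection(
                t_start_s=i0 / fs,
                t_end_s=i1 / fs,
                t_peak_s=ipeak / fs,
                detector="ste",
                type="oscillation",
                score=float(rms[ipeak]),
            )
        )
    return DetectorOutput(detections, thr, {"rect_threshold": rect_thr})
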