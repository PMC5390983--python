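"""MNI two-stage detector.

Stage 1 scans the band-passed record in 125 ms windows and computes the
wavelet entropy (WE) of each window's autocorrelation: broadband
(baseline-like) windows score near the theoretical maximum, rhythmic or
semi-continuous high-frequency windows score low.  If enough baseline is
found, the energy threshold is the 99.9999th percentile of the RMS values
inside baseline windows.  Otherwise (no-baseline mode) an STE-like threshold
is re-estimated iteratively after removing previously detected events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import tf as hft
from .base import (
    Detection,
    DetectorOutput,
    bandpass_80_500,
    edge_mask,
    merge_runs,
    moving_rms,
    runs_above,
)

__all__ = ["MNIParams", "detect_mni"]


@dataclass
class MNIParams:
    baseline_window_s: float = 0.125
    # calibrated on the synthetic channel families: 1/f-like backgrounds put
    # 25-28% of their windows above 0.55 x max entropy, semi-continuous
    # high-frequency backgrounds 7-11% (entropy is PSD-dependent, so the
    # usable threshold depends on the wavelet-entropy implementation)
    we_threshold_frac: float = 0.55
    min_baseline_frac: float = 0.15  # minimum share of baseline windows
    baseline_percentile: float = 99.9999  # near the maximum order statistic
    percentile_method: str = "linear"  # numpy interpolation convention
    rms_window_s: float = 0.003
    min_duration_s: float = 0.010
    merge_gap_s: float = 0.010
    iterative_threshold_sd: float = 5.0
    max_iterations: int = 10
    rel_tol: float = 0.005
    we_scales_hz: tuple[float, ...] = hft.DEFAULT_WE_SCALES_HZ


def _detect_from_threshold(
    rms: np.ndarray, thr: float, valid: np.ndarray, fs: float, params: MNIParams
) -> list[tuple[int, int]]:
    min_len = int(round(params.min_duration_s * fs))
    segs = merge_runs(
        runs_above((rms > thr) & valid), int(round(params.merge_gap_s * fs))
    )
    return [(i0, i1) for i0, i1 in segs if i1 - i0 >= min_len]


def detect_mni(
    signal: np.ndarray,
    fs: float,
    params: MNIParams | None = None,
    prefiltered: bool = False,
) -> DetectorOutput:
    params = params or MNIParams()
    x = np.asarray(signal, dtype=float)
    if x.size < 10 * fs:
        raise ValueError("MNI needs at least 10 s of signal for baseline statistics")
    bp = x if prefiltered else bandpass_80_500(x, fs)
    rms = moving_rms(bp, max(1, int(round(params.rms_window_s * fs))))
    valid = edge_mask(x.size, fs)

    # stage 1: baseline hunting by wavelet entropy of the autocorrelation
    _, we = hft.wavelet_entropy_profile(
        bp, fs, window_s=params.baseline_window_s, scales_hz=params.we_scales_hz
    )
    we_max = hft.wavelet_entropy_max(len(params.we_scales_hz))
    baseline_windows = we > params.we_threshold_frac * we_max
    baseline_frac = float(np.mean(baseline_windows)) if baseline_windows.size else 0.0

    wlen = int(round(params.baseline_window_s * fs))
    extras: dict = {"baseline_fraction": baseline_frac, "we_max": we_max}
    if baseline_frac >= params.min_baseline_frac:
        mode = "baseline"
        bl_mask = np.zeros(x.size, dtype=bool)
        for i in np.flatnonzero(baseline_windows):
            bl_mask[i * wlen : (i + 1) * wlen] = True
        samples = rms[bl_mask & valid]
        thr = float(
            np.percentile(samples, params.baseline_percentile, method=params.percentile_method)
        )
        segs = _detect_from_threshold(rms, thr, valid, fs, params)
    else:
        mode = "iterative"
        keep = valid.copy()
        thr = float(rms[keep].mean() + params.iterative_threshold_sd * rms[keep].std())
        history = [thr]
        for _ in range(params.max_iterations):
            segs = _detect_from_threshold(rms, thr, valid, fs, params)
            keep = valid.copy()
            for i0, i1 in segs:
                keep[i0:i1] = False
            new_thr = float(
                rms[keep].mean() + params.iterative_threshold_sd * rms[keep].std()
            )
            history.append(new_thr)
            if abs(new_thr - thr) <= params.rel_tol * thr:
                thr = new_thr
                break
            thr = new_thr
        segs = _detect_from_threshold(rms, thr, valid, fs, params)
        extras["threshold_history"] = history

    extras["mode"] = mode
    detections = []
    for i0, i1 in segs:
        ipeak = i0 + int(np.argmax(rms[i0:i1]))
        detections.append(
            Detection(
                t_start_s=i0 / fs,
                t_end_s=i1 / fs,
                t_peak_s=ipeak / fs,
                detector="mni",
                type="oscillation",
                score=float(rms[ipeak]),
            )
        )
    return DetectorOutput(detections, thr, extras)
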