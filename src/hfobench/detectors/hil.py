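"""Hilbert-envelope (HIL) detector.

Envelope of the band-passed signal via the analytic signal; stretches where
the envelope exceeds mean + 5 SD of the whole-record envelope for at least
10 ms are detections.  A ``pure_sd`` flag switches to a bare 5 SD threshold
(without the mean) for the alternative reading of the rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy.signal import hilbert

from .base import Detection, DetectorOutput, bandpass_80_500, edge_mask, runs_above

__all__ = ["HILParams", "detect_hil"]


@dataclass
class HILParams:
    threshold_sd: float = 5.0
    min_duration_s: float = 0.010
    pure_sd: bool = False


def envelope(x: np.ndarray) -> np.ndarray:
    n = x.size
    nfft = sp_fft.next_fast_len(n)
    return np.abs(hilbert(x, N=nfft)[:n])


def detect_hil(
    signal: np.ndarray,
    fs: float,
    params: HILParams | None = None,
    prefiltered: bool = False,
) -> DetectorOutput:
    params = params or HILParams()
    x = np.asarray(signal, dtype=float)
    bp = x if prefiltered else bandpass_80_500(x, fs)
    env = envelope(bp)
    valid = edge_mask(x.size, fs)
    mu, sd = float(env[valid].mean()), float(env[valid].std())
    thr = params.threshold_sd * sd if params.pure_sd else mu + params.threshold_sd * sd
    min_len = int(round(params.min_duration_s * fs))
    detections = []
    if sd > 0:  # a constant envelope (unmodulated tone) yields no detections
        for i0, i1 in runs_above((env > thr) & valid):
            if i1 - i0 < min_len:
                continue
            ipeak = i0 + int(np.argmax(env[i0:i1]))
            detections.append(
                Detection(
                    t_start_s=i0 / fs,
                    t_end_s=i1 / fs,
                    t_peak_s=ipeak / fs,
                    detector="hil",
                    type="oscillation",
                    score=float(env[ipeak]),
                )
            )
    return DetectorOutput(detections, float(thr), {"envelope_mean": mu, "envelope_sd": sd})
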