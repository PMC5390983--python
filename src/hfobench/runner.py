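"""In-memory benchmark orchestration: simulate -> detect -> score.

Convenience layer used by the acceptance suite and the examples; the CLI
drives the same pipeline through files on disk instead.
"""

from __future__ import annotations

import logging

import numpy as np

from .background import ARBackgroundModel
from .detectors import run_detector
from .evaluation import match_detections
from .events import EventTemplate
from .simulate import SimulationConfig, generate_channel, realization_seed

__all__ = ["run_benchmark_in_memory", "pool_counts", "pooled_kind_sensitivity", "mean_thresholds"]

log = logging.getLogger(__name__)


def run_benchmark_in_memory(
    models: list[ARBackgroundModel],
    dictionary: list[EventTemplate],
    config: SimulationConfig,
    detector_names: tuple[str, ...] = ("ste", "sll", "hil", "mni", "delphos"),
) -> list[dict]:
    """Generate every record of the benchmark grid and score each detector.

    Returns one row per (record, detector) with the MatchResult, the
    detector's threshold and its extras, ready for
    :func:`hfobench.evaluation.benchmark_report`.
    """
    results = []
    for ci, model in enumerate(models):
        for si, snr in enumerate(config.snr_grid_db):
            for ri in range(config.n_realizations):
                seed = realization_seed(config.seed, ci, si, ri)
                chan = generate_channel(model, dictionary, config, snr, seed)
                for name in detector_names:
                    out = run_detector(name, chan.samples, chan.fs)
                    m = match_detections(chan.ground_truth, out.detections)
                    results.append(
                        {
                            "detector": name,
                            "channel_id": model.channel_id,
                            "snr_db": snr,
                            "realization": ri,
                            "match": m,
                            "threshold": out.threshold,
                            "extras": out.extras,
                        }
                    )
        log.info("channel %s scored", model.channel_id)
    return results


def pool_counts(results: list[dict], detector: str) -> dict[float, tuple[int, int, int]]:
    """Pooled (TP, FP, FN) per SNR for one detector (micro-average)."""
    acc: dict[float, list[int]] = {}
    for r in results:
        if r["detector"] != detector:
            continue
        a = acc.setdefault(r["snr_db"], [0, 0, 0])
        m = r["match"]
        a[0] += m.tp
        a[1] += m.fp
        a[2] += m.fn
    return {snr: tuple(v) for snr, v in sorted(acc.items())}


def pooled_kind_sensitivity(
    results: list[dict], detector: str, snr_db: float
) -> dict[str, float]:
    """Sensitivity pooled over records, split by component kind (R vs FR)."""
    counts = {"R": [0, 0], "FR": [0, 0]}  # matched, total
    for r in results:
        if r["detector"] != detector or r["snr_db"] != snr_db:
            continue
        m = r["match"]
        matched = m.matched_ci_indices()
        for i, ci in enumerate(m.cis):
            counts[ci.kind][1] += 1
            counts[ci.kind][0] += i in matched
    return {k: (v[0] / v[1] if v[1] else float("nan")) for k, v in counts.items()}


def mean_thresholds(results: list[dict], detector: str) -> dict[float, float]:
    """Mean reported threshold per SNR for one detector."""
    acc: dict[float, list[float]] = {}
    for r in results:
        if r["detector"] == detector:
            acc.setdefault(r["snr_db"], []).append(r["threshold"])
    return {snr: float(np.mean(v)) for snr, v in sorted(acc.items())}
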