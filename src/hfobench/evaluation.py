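"""Scoring detections against ground truth with 100 ms confidence intervals.

A confidence interval (CI) is a 100 ms window centred on each inserted HFO
component (R/FR only -- inserted pure spikes get no CI, so detections they
trigger count as false positives).  A CI containing at least one overlapping
detection is a true positive, an empty CI a false negative, and a detection
overlapping no CI a false positive.  Sensitivity = TP/(TP+FN),
precision = TP/(TP+FP), F = harmonic mean of the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detectors.base import Detection
from .simulate import GroundTruthEvent

__all__ = [
    "ConfidenceInterval",
    "MatchResult",
    "build_cis",
    "match_detections",
    "compute_metrics",
    "per_class_sensitivity",
    "benchmark_report",
]

DEFAULT_CI_MS = 100.0
HFO_CLASSES = (2, 3, 4, 5, 6, 7)


@dataclass
class ConfidenceInterval:
    center_s: float
    class_id: int
    kind: str  # R | FR

    def bounds(self, ci_ms: float = DEFAULT_CI_MS) -> tuple[float, float]:
        half = ci_ms / 2000.0
        return self.center_s - half, self.center_s + half


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    cis: list[ConfidenceInterval]
    assignments: dict[int, list[int]]  # ci index -> matched detection indices
    ci_ms: float = DEFAULT_CI_MS

    def matched_ci_indices(self) -> set[int]:
        return {i for i, dets in self.assignments.items() if dets}


def build_cis(
    ground_truth: list[GroundTruthEvent], ci_ms: float = DEFAULT_CI_MS
) -> list[ConfidenceInterval]:
    """One CI per inserted HFO component, centred on its actual (jittered)
    insertion time.  Overlapping CIs indicate a generator misconfiguration
    and raise."""
    cis = [
        ConfidenceInterval(c.t_center_s, ev.class_id, c.kind)
        for ev in ground_truth
        for c in ev.components
        if c.kind in ("R", "FR")
    ]
    cis.sort(key=lambda c: c.center_s)
    for a, b in zip(cis, cis[1:]):
        # components of one composite event share a CI window legitimately
        same_event = abs(a.center_s - b.center_s) <= 2 * 0.020 + 1e-9
        if not same_event and a.bounds(ci_ms)[1] > b.bounds(ci_ms)[0]:
            raise ValueError(
                f"overlapping CIs at {a.center_s:.3f}s and {b.center_s:.3f}s: "
                "generator spacing guarantee violated"
            )
    return cis


def _overlaps(det: Detection, lo: float, hi: float) -> bool:
    return det.t_start_s < hi and det.t_end_s > lo


def match_detections(
    ground_truth: list[GroundTruthEvent],
    detections: list[Detection],
    ci_ms: float = DEFAULT_CI_MS,
) -> MatchResult:
    """Assign detections to CIs by interval overlap.

    Each detection goes to at most one CI and the assignment maximizes the
    number of matched CIs (maximum bipartite matching; nearest centre breaks
    ties among equivalent assignments).  A CI with any match counts once as
    TP regardless of how many detections landed in it, so surplus matched
    detections are neither TP nor FP; detections overlapping no CI are FP.
    """
    cis = build_cis(ground_truth, ci_ms)
    overlap: list[list[int]] = []
    fp = 0
    for det in detections:
        hits = [ci_i for ci_i, ci in enumerate(cis) if _overlaps(det, *ci.bounds(ci_ms))]
        if not hits:
            fp += 1
        overlap.append(hits)
    if cis and detections:
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import maximum_bipartite_matching

        rows = [di for di, hits in enumerate(overlap) for _ in hits]
        cols = [ci_i for hits in overlap for ci_i in hits]
        graph = csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)),
            shape=(len(detections), len(cis)),
        )
        match_for_ci = maximum_bipartite_matching(graph, perm_type="row")
    else:
        match_for_ci = np.full(len(cis), -1)
    assignments: dict[int, list[int]] = {i: [] for i in range(len(cis))}
    assigned_dets: set[int] = set()
    for ci_i, di in enumerate(match_for_ci):
        if di >= 0:
            assignments[ci_i].append(int(di))
            assigned_dets.add(int(di))
    # surplus detections: overlap at least one CI but were not needed for the
    # matching; attach to their nearest overlapped CI (neither TP nor FP)
    for di, hits in enumerate(overlap):
        if hits and di not in assigned_dets:
            det = detections[di]
            det_mid = 0.5 * (det.t_start_s + det.t_end_s)
            best = min(hits, key=lambda ci_i: (abs(cis[ci_i].center_s - det_mid), ci_i))
            assignments[best].append(di)
    tp = int(np.sum(match_for_ci >= 0))
    fn = len(cis) - tp
    return MatchResult(tp=tp, fp=fp, fn=fn, cis=cis, assignments=assignments, ci_ms=ci_ms)


def compute_metrics(m: MatchResult) -> tuple[float, float | None, float | None]:
    """(sensitivity, precision, F-measure) with 0/0 cases reported as None.

    Precision is undefined (None) when there are no detections at all;
    F is None whenever either component is.
    """
    if min(m.tp, m.fp, m.fn) < 0:
        raise ValueError("negative counts")
    positives = m.tp + m.fn
    sens = m.tp / positives if positives > 0 else None
    prec = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else None
    if sens is None or prec is None or (sens + prec) == 0:
        f = 0.0 if (sens == 0 or prec == 0) and None not in (sens, prec) else None
    else:
        f = 2 * prec * sens / (prec + sens)
    return sens, prec, f


def per_class_sensitivity(m: MatchResult) -> dict[int, float | None]:
    """Sensitivity per event class, one CI per HFO component.

    Composite classes contribute one CI per component (class 4 and 7 carry
    both an R and an FR CI).  Classes with no inserted events report None.
    """
    matched = m.matched_ci_indices()
    out: dict[int, float | None] = {}
    for cls in HFO_CLASSES:
        idx = [i for i, ci in enumerate(m.cis) if ci.class_id == cls]
        if not idx:
            out[cls] = None
        else:
            out[cls] = sum(1 for i in idx if i in matched) / len(idx)
    for ci in m.cis:
        if ci.class_id not in HFO_CLASSES:
            raise ValueError(f"unknown HFO-bearing class id {ci.class_id}")
    return out


def per_kind_sensitivity(m: MatchResult) -> dict[str, float | None]:
    """Sensitivity pooled by component kind (R vs FR)."""
    matched = m.matched_ci_indices()
    out: dict[str, float | None] = {}
    for kind in ("R", "FR"):
        idx = [i for i, ci in enumerate(m.cis) if ci.kind == kind]
        out[kind] = (
            sum(1 for i in idx if i in matched) / len(idx) if idx else None
        )
    return out


def benchmark_report(
    results: list[dict],
    out_dir=None,
) -> dict[str, pd.DataFrame]:
    """Aggregate per-record match results into the benchmark tables.

    ``results`` rows need keys: detector, channel_id, snr_db, realization,
    match (MatchResult), threshold.  Returns metrics / per_class /
    thresholds DataFrames and optionally writes them as TSV plus a summary
    JSON to ``out_dir``.
    """
    metric_rows, class_rows, thr_rows = [], [], []
    for r in results:
        m: MatchResult = r["match"]
        sens, prec, f = compute_metrics(m)
        base = {
            "detector": r["detector"],
            "channel_id": r["channel_id"],
            "snr_db": r["snr_db"],
            "realization": r["realization"],
        }
        metric_rows.append(
            base | {"tp": m.tp, "fp": m.fp, "fn": m.fn, "sens": sens, "prec": prec, "f": f}
        )
        for cls, s in per_class_sensitivity(m).items():
            class_rows.append(base | {"class_id": cls, "sensitivity": s})
        thr_rows.append(base | {"threshold": r.get("threshold", np.nan)})
    tables = {
        "metrics": pd.DataFrame(metric_rows),
        "per_class": pd.DataFrame(class_rows),
        "thresholds": pd.DataFrame(thr_rows),
    }
    if out_dir is not None:
        from pathlib import Path
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        pooled = (
            tables["metrics"]
            .groupby(["detector", "snr_db"])[["tp", "fp", "fn"]]
            .sum()
            .reset_index()
        )
        pooled["sens"] = pooled.tp / (pooled.tp + pooled.fn)
        pooled["prec"] = pooled.tp / (pooled.tp + pooled.fp).replace(0, np.nan)
        with open(out / "summary.json", "w") as fh:
            json.dump(pooled.to_dict(orient="records"), fh, indent=1)
    return tables
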