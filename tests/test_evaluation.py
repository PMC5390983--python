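"""Confidence-interval matching and the benchmark metrics."""

import itertools

import numpy as np
import pytest

from hfobench.detectors.base import Detection
from hfobench.evaluation import (
    MatchResult,
    benchmark_report,
    build_cis,
    compute_metrics,
    match_detections,
    per_class_sensitivity,
)
from hfobench.simulate import GroundTruthComponent, GroundTruthEvent


def _gt(centers_kinds):
    """Ground truth with isolated single-component events."""
    events = []
    for t, kind, cls in centers_kinds:
        events.append(GroundTruthEvent(cls, t, [GroundTruthComponent(kind, t, 10.0)]))
    return events


def _det(t0, t1, name="x"):
    return Detection(t_start_s=t0, t_end_s=t1, t_peak_s=(t0 + t1) / 2, detector=name)


class TestMatching:
    def test_ci_boundary_overlap_rule(self):
        gt = _gt([(5.0, "R", 5)])
        # 10 ms detection centred 49 ms after the CI centre: still overlaps
        tp = match_detections(gt, [_det(5.044, 5.054)])
        assert (tp.tp, tp.fp, tp.fn) == (1, 0, 0)
        # same detection 80 ms out: no overlap with the 100 ms window
        fp = match_detections(gt, [_det(5.075, 5.085)])
        assert (fp.tp, fp.fp, fp.fn) == (0, 1, 1)

    def test_no_detections_all_fn(self):
        gt = _gt([(float(t), "R", 5) for t in range(1, 11)])
        m = match_detections(gt, [])
        assert (m.tp, m.fp, m.fn) == (0, 0, 10)
        sens, prec, f = compute_metrics(m)
        assert sens == 0.0 and prec is None and f is None

    def test_surplus_detections_in_one_ci_count_once(self):
        gt = _gt([(5.0, "R", 5)])
        dets = [_det(4.99, 5.01), _det(5.0, 5.02), _det(5.01, 5.03)]
        m = match_detections(gt, dets)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_spike_components_get_no_ci(self):
        ev = GroundTruthEvent(1, 3.0, [GroundTruthComponent("SPK", 3.0, 5.0)])
        m = match_detections([ev], [_det(2.99, 3.01)])
        assert (m.tp, m.fp, m.fn) == (0, 1, 0)

    def test_overlapping_cis_rejected(self):
        gt = _gt([(5.0, "R", 5), (5.06, "FR", 6)])
        with pytest.raises(ValueError, match="overlapping CIs"):
            build_cis(gt)

    def test_detection_order_does_not_change_counts(self, rng):
        gt = _gt([(float(t), "R", 5) for t in (1, 2, 3, 4)])
        dets = [_det(0.98, 1.02), _det(2.51, 2.55), _det(3.99, 4.01), _det(1.5, 1.6)]
        base = match_detections(gt, dets)
        for perm in itertools.permutations(range(4)):
            m = match_detections(gt, [dets[i] for i in perm])
            assert (m.tp, m.fp, m.fn) == (base.tp, base.fp, base.fn)

    def test_far_detection_increments_fp_only(self):
        gt = _gt([(1.0, "R", 5), (2.0, "FR", 6)])
        dets = [_det(0.99, 1.01)]
        before = match_detections(gt, dets)
        after = match_detections(gt, dets + [_det(5.0, 5.01)])
        assert after.fp == before.fp + 1
        assert (after.tp, after.fn) == (before.tp, before.fn)


def _brute_force_counts(cis_bounds, det_bounds):
    """Exhaustive assignment oracle: each detection goes to at most one
    overlapping CI; maximize the number of CIs holding >= 1 detection."""

    def overlaps(d, c):
        return d[0] < c[1] and d[1] > c[0]

    n_det = len(det_bounds)
    options = [
        [None] + [ci for ci, c in enumerate(cis_bounds) if overlaps(d, c)]
        for d in det_bounds
    ]
    best_tp = 0
    for choice in itertools.product(*options):
        hit = {c for c in choice if c is not None}
        best_tp = max(best_tp, len(hit))
    fp = sum(1 for opts in options if len(opts) == 1)
    fn = len(cis_bounds) - best_tp
    return best_tp, fp, fn


def test_matcher_equals_brute_force_on_random_instances():
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        n_ci = rng.integers(0, 9)
        n_det = rng.integers(0, 9)
        centers = np.sort(rng.choice(np.arange(40), size=n_ci, replace=False)) * 0.6 + 1.0
        gt = _gt([(float(c), "R", 5) for c in centers])
        dets = []
        for _ in range(n_det):
            t0 = float(rng.uniform(0.0, 26.0))
            dets.append(_det(t0, t0 + float(rng.uniform(0.005, 0.3))))
        m = match_detections(gt, dets)
        cis_bounds = [ci.bounds() for ci in m.cis]
        det_bounds = [(d.t_start_s, d.t_end_s) for d in dets]
        assert (m.tp, m.fp, m.fn) == _brute_force_counts(cis_bounds, det_bounds)


class TestMetrics:
    @pytest.mark.parametrize(
        "tp,fn,fp,sens,prec,f",
        [
            (30, 0, 0, 1.0, 1.0, 1.0),
            (15, 15, 5, 0.5, 0.75, 0.6),
            (0, 10, 3, 0.0, 0.0, 0.0),
        ],
    )
    def test_metric_arithmetic(self, tp, fn, fp, sens, prec, f):
        m = MatchResult(tp=tp, fp=fp, fn=fn, cis=[], assignments={})
        s, p, fm = compute_metrics(m)
        assert s == pytest.approx(sens)
        assert p == pytest.approx(prec)
        assert fm == pytest.approx(f)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(MatchResult(tp=-1, fp=0, fn=0, cis=[], assignments={}))


class TestPerClass:
    def test_all_matched_gives_unit_sensitivity(self):
        gt = _gt([(1.0, "R", 5), (2.0, "FR", 6)])
        m = match_detections(gt, [_det(0.99, 1.01), _det(1.99, 2.01)])
        pcs = per_class_sensitivity(m)
        assert pcs[5] == 1.0 and pcs[6] == 1.0
        assert pcs[2] is None  # class with no inserted events

    def test_r_band_only_detector(self):
        gt = [
            GroundTruthEvent(
                2, 1.0, [GroundTruthComponent("SPK", 1.0, 5.0), GroundTruthComponent("R", 1.0, 10.0)]
            ),
            GroundTruthEvent(
                3, 2.0, [GroundTruthComponent("SPK", 2.0, 5.0), GroundTruthComponent("FR", 2.0, 10.0)]
            ),
            GroundTruthEvent(5, 3.0, [GroundTruthComponent("R", 3.0, 10.0)]),
            GroundTruthEvent(6, 4.0, [GroundTruthComponent("FR", 4.0, 10.0)]),
        ]
        dets = [_det(0.99, 1.01), _det(2.99, 3.01)]  # fires in R CIs only
        pcs = per_class_sensitivity(match_detections(gt, dets))
        assert pcs[2] == 1.0 and pcs[5] == 1.0
        assert pcs[3] == 0.0 and pcs[6] == 0.0

    def test_weighted_class_sensitivities_recover_overall(self):
        gt = _gt([(float(t), "R" if t % 2 else "FR", 5 if t % 2 else 6) for t in range(1, 9)])
        dets = [_det(t - 0.01, t + 0.01) for t in (1.0, 2.0, 5.0)]
        m = match_detections(gt, dets)
        pcs = per_class_sensitivity(m)
        counts = {cls: sum(1 for ci in m.cis if ci.class_id == cls) for cls in pcs}
        num = sum(pcs[c] * counts[c] for c in pcs if pcs[c] is not None)
        den = sum(counts[c] for c in pcs if pcs[c] is not None)
        sens, _, _ = compute_metrics(m)
        assert num / den == pytest.approx(sens)


class TestReport:
    def _results(self):
        gt = _gt([(1.0, "R", 5)])
        m = match_detections(gt, [_det(0.99, 1.01)])
        rows = []
        for det in ("a", "b"):
            for snr in (0.0, 15.0):
                for ri in range(3):
                    rows.append(
                        {
                            "detector": det,
                            "channel_id": "c1",
                            "snr_db": snr,
                            "realization": ri,
                            "match": m,
                            "threshold": 1.0,
                        }
                    )
        return rows

    def test_row_counting(self, tmp_path):
        tables = benchmark_report(self._results(), tmp_path)
        assert len(tables["metrics"]) == 12
        assert (tmp_path / "metrics.tsv").exists()
        assert (tmp_path / "summary.json").exists()

    def test_perfect_detector_scores_one_everywhere(self):
        tables = benchmark_report(self._results())
        assert (tables["metrics"]["sens"] == 1.0).all()
        assert (tables["metrics"]["prec"] == 1.0).all()
        assert (tables["metrics"]["f"] == 1.0).all()
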