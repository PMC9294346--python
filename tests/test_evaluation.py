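"""IoU matching, VOC2010 average precision, and the F1 threshold sweep."""

import itertools

import numpy as np
import pytest

from osteoquant.annotation_io import DetectionRecord
from osteoquant.evaluation import (
    MatchTable,
    average_precision,
    iou,
    match,
    precision_recall_f1,
    sweep_thresholds,
)
from osteoquant.tiles import GTBox


def det(cx, cy, w=10.0, h=10.0, conf=0.9):
    return DetectionRecord(cx=cx, cy=cy, w=w, h=h, confidence=conf)


def gt(cx, cy, w=10.0, h=10.0):
    return GTBox(cx, cy, w, h)


def ap_step_integration_oracle(flags, n_gt, dr=1e-3):
    """Independent AP oracle: numerically integrate the precision envelope."""
    tp = np.cumsum(flags)
    rec = tp / n_gt
    prec = tp / np.arange(1, len(flags) + 1)
    grid = np.arange(dr / 2, 1.0, dr)
    env = np.array([prec[rec >= r].max() if (rec >= r).any() else 0.0 for r in grid])
    return float(env.sum() * dr)


class TestIoU:
    def test_identical_boxes(self):
        assert iou(gt(5, 5), gt(5, 5)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(gt(0, 0), gt(100, 100)) == 0.0

    def test_half_overlap_arithmetic(self):
        a = gt(50, 50, 100, 100)     # corners (0,0)-(100,100)
        b = gt(100, 50, 100, 100)    # corners (50,0)-(150,100)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_symmetry(self, rng):
        for _ in range(50):
            a = gt(*rng.uniform(0, 100, 2), *rng.uniform(1, 50, 2))
            b = gt(*rng.uniform(0, 100, 2), *rng.uniform(1, 50, 2))
            assert iou(a, b) == pytest.approx(iou(b, a))


class TestMatch:
    def test_single_overlapping_detection_is_tp(self):
        table = match([det(5, 5, conf=0.8)], [gt(7, 5)], 0.1)
        assert table.is_tp == [True]

    def test_duplicate_detection_of_matched_gt_is_fp(self):
        table = match([det(5, 5, conf=0.9), det(6, 5, conf=0.5)], [gt(5, 5)], 0.1)
        assert table.is_tp == [True, False]

    def test_greedy_flags_match_exhaustive_oracle(self, rng):
        # brute-force the same greedy rule over explicitly sorted detections
        for _ in range(50):
            dets = [det(float(rng.uniform(0, 40)), float(rng.uniform(0, 40)),
                        conf=float(rng.uniform(0, 1))) for _ in range(3)]
            gts = [gt(float(rng.uniform(0, 40)), float(rng.uniform(0, 40)))
                   for _ in range(2)]
            expect = []
            order = sorted(dets, key=lambda d: (-d.confidence, d.cx, d.cy))
            used = set()
            for d in order:
                cands = [(iou(d, g), j) for j, g in enumerate(gts) if j not in used]
                best = max(cands, key=lambda t: t[0]) if cands else (0.0, -1)
                hit = best[0] >= 0.1
                expect.append(hit)
                if hit:
                    used.add(best[1])
            assert match(dets, gts, 0.1).is_tp == expect

    def test_each_gt_matched_at_most_once(self, rng):
        dets = [det(10, 10, conf=c) for c in (0.9, 0.8, 0.7)]
        table = match(dets, [gt(10, 10), gt(11, 10)], 0.1)
        assert table.n_tp <= 2


class TestAveragePrecision:
    def test_perfect_detections_give_ap_one(self):
        table = match([det(5, 5, conf=0.9), det(50, 50, conf=0.8)],
                      [gt(5, 5), gt(50, 50)], 0.1)
        assert average_precision(table).ap == 1.0

    def test_single_false_positive_gives_ap_zero(self):
        table = match([det(500, 500, conf=0.9)], [gt(5, 5)], 0.1)
        assert average_precision(table).ap == 0.0

    def test_tp_fp_tp_envelope_area_is_five_sixths(self):
        table = MatchTable(
            detections=[det(0, 0, conf=0.9), det(1, 0, conf=0.8), det(2, 0, conf=0.7)],
            is_tp=[True, False, True], n_ground_truth=2, iou_threshold=0.1)
        curve = average_precision(table)
        assert curve.ap == pytest.approx(5 / 6)
        assert curve.precision == pytest.approx([1.0, 0.5, 2 / 3])
        assert curve.recall == pytest.approx([0.5, 0.5, 1.0])

    def test_zero_ground_truth_rejected(self):
        with pytest.raises(ValueError, match="zero ground-truth"):
            average_precision(MatchTable([], [], 0, 0.1))

    def test_ap_matches_step_integration_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n_gt = int(rng.integers(1, 6))
            n_det = int(rng.integers(1, 11))
            flags = list(rng.random(n_det) < 0.5)
            # cap TPs at n_gt, as matching would
            while sum(flags) > n_gt:
                flags[flags.index(True)] = False
            table = MatchTable([det(i, 0, conf=1 - i * 0.01) for i in range(n_det)],
                               flags, n_gt, 0.1)
            ap = average_precision(table).ap
            assert ap == pytest.approx(ap_step_integration_oracle(flags, n_gt), abs=2e-3)

    def test_inserting_fp_at_any_rank_never_increases_ap(self):
        base = [True, True, False, True]
        n_gt = 4
        ranked = lambda flags: MatchTable(
            [det(i, 0, conf=1 - 0.01 * i) for i in range(len(flags))],
            flags, n_gt, 0.1)
        ap0 = average_precision(ranked(base)).ap
        for pos in range(len(base) + 1):
            flags = base[:pos] + [False] + base[pos:]
            assert average_precision(ranked(flags)).ap <= ap0 + 1e-12

    def test_stricter_iou_never_raises_ap(self, rng):
        for _ in range(40):
            dets = [det(float(rng.uniform(0, 60)), float(rng.uniform(0, 60)),
                        conf=float(rng.uniform(0, 1))) for _ in range(8)]
            gts = [gt(float(rng.uniform(0, 60)), float(rng.uniform(0, 60)))
                   for _ in range(4)]
            ap_loose = average_precision(match(dets, gts, 0.1)).ap
            ap_strict = average_precision(match(dets, gts, 0.5)).ap
            assert ap_strict <= ap_loose + 1e-12


class TestSweep:
    def test_perfect_detector_best_threshold_is_zero(self):
        gts = [gt(10 * i, 5) for i in range(1, 4)]
        dets = [det(g.cx, g.cy, conf=1.0) for g in gts]
        rows, best = sweep_thresholds(dets, gts, 0.1)
        assert best == 0.0
        assert all(r.f1 == pytest.approx(1.0) for r in rows)
        assert len(rows) == 21  # 0, 0.05, ..., 1 inclusive

    def test_best_threshold_separates_good_from_spurious(self):
        gts = [gt(20 * i, 5) for i in range(1, 6)]
        good = [det(g.cx, g.cy, conf=0.6) for g in gts]
        spurious = [det(500 + 20 * i, 500, conf=0.4) for i in range(5)]
        _, best = sweep_thresholds(good + spurious, gts, 0.1)
        assert 0.4 < best <= 0.6

    def test_no_detections_give_zero_scores_everywhere(self):
        rows, best = sweep_thresholds([], [gt(5, 5)], 0.1)
        assert best == 0.0
        assert all(r.precision == r.recall == r.f1 == 0.0 for r in rows)

    def test_f1_identity_holds_per_row(self, rng):
        dets = [det(float(rng.uniform(0, 100)), float(rng.uniform(0, 100)),
                    conf=float(rng.uniform(0, 1))) for _ in range(12)]
        gts = [gt(float(rng.uniform(0, 100)), float(rng.uniform(0, 100)))
               for _ in range(6)]
        rows, _ = sweep_thresholds(dets, gts, 0.1)
        for r in rows:
            expect = (2 * r.precision * r.recall / (r.precision + r.recall)
                      if r.precision + r.recall > 0 else 0.0)
            assert r.f1 == pytest.approx(expect)
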