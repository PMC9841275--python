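"""Detection evaluation: IOU, matching, PR curves, AP/mAP, reliability."""

import numpy as np
import pytest
from shapely.geometry import box as shapely_box

from pentrack.detection_eval import (
    BoundingBox,
    annotator_reliability,
    average_precision,
    boxes_by_frame,
    iou,
    map_over,
    match_frame,
    pr_curve,
    PRPoint,
)


def bb(cx, cy, w=10.0, h=10.0, cls="a", conf=None):
    return BoundingBox(cx=cx, cy=cy, w=w, h=h, cls=cls, conf=conf)


def shapely_iou(a: BoundingBox, b: BoundingBox) -> float:
    ra = shapely_box(a.left, a.top, a.right, a.bottom)
    rb = shapely_box(b.left, b.top, b.right, b.bottom)
    union = ra.union(rb).area
    return ra.intersection(rb).area / union if union else 0.0


class TestIou:
    def test_identical_boxes(self):
        assert iou(bb(5, 5), bb(5, 5)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(bb(0, 0), bb(100, 100)) == 0.0

    def test_half_side_offset_unit_squares(self):
        # overlap 0.5, union 1.5 -> exactly 1/3
        a = bb(0.0, 0.0, 1.0, 1.0)
        b = bb(0.5, 0.0, 1.0, 1.0)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(cx=0, cy=0, w=0.0, h=5.0)

    def test_symmetric_and_matches_shapely_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = bb(*rng.integers(0, 50, 2), *rng.integers(1, 30, 2))
            b = bb(*rng.integers(0, 50, 2), *rng.integers(1, 30, 2))
            v = iou(a, b)
            assert v == pytest.approx(iou(b, a))
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(shapely_iou(a, b), abs=1e-9)


class TestMatchFrame:
    def test_perfect_predictions(self):
        gts = [bb(10, 10), bb(40, 40)]
        preds = [bb(10, 10, conf=0.9), bb(40, 40, conf=0.8)]
        assert match_frame(preds, gts, 0.5, 0.5) == (2, 0, 0)

    def test_low_iou_is_fp_and_fn(self):
        gt = bb(0, 0, 10, 10)
        pred = bb(6, 0, 10, 10, conf=0.9)  # IOU = 4/16 = 0.25
        assert iou(pred, gt) < 0.5
        assert match_frame([pred], [gt], 0.5, 0.5) == (0, 1, 1)

    def test_duplicate_predictions_one_tp_one_fp(self):
        gt = bb(10, 10)
        preds = [bb(10, 10, conf=0.9), bb(11, 10, conf=0.8)]
        assert match_frame(preds, gts=[gt], conf_t=0.5, iou_t=0.5) == (1, 1, 0)

    def test_wrong_class_is_fp(self):
        gt = bb(10, 10, cls="a")
        pred = bb(10, 10, cls="c", conf=0.9)
        assert match_frame([pred], [gt], 0.5, 0.5) == (0, 1, 1)

    def test_confidence_threshold_discards(self):
        gt = bb(10, 10)
        pred = bb(10, 10, conf=0.4)
        assert match_frame([pred], [gt], 0.5, 0.5) == (0, 0, 1)

    def test_counting_invariants_random(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            gts = [bb(*rng.integers(0, 60, 2)) for _ in range(rng.integers(1, 5))]
            preds = [
                bb(*rng.integers(0, 60, 2), conf=float(rng.random()))
                for _ in range(rng.integers(0, 6))
            ]
            conf_t = float(rng.random())
            tp, fp, fn = match_frame(preds, gts, conf_t, 0.5)
            assert tp + fn == len(gts)
            assert tp + fp == sum(1 for p in preds if p.conf >= conf_t)
            # raising the confidence threshold never increases tp
            tp_hi, _, _ = match_frame(preds, gts, min(conf_t + 0.2, 1.0), 0.5)
            assert tp_hi <= tp


class TestPrCurve:
    def test_precision_at_single_threshold(self):
        # 9 matched + 1 unmatched prediction at one confidence -> p = 0.9
        gts = {0: [bb(10 * i, 0) for i in range(9)]}
        preds = {0: [bb(10 * i, 0, conf=0.8) for i in range(9)] + [bb(500, 500, conf=0.8)]}
        (pt,) = pr_curve(preds, gts, 0.5)
        assert pt.precision == pytest.approx(0.9)
        assert pt.recall == 1.0

    def test_matches_per_threshold_recount_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            gts, preds = {}, {}
            for f in range(3):
                gts[f] = [bb(*rng.integers(0, 50, 2)) for _ in range(rng.integers(1, 4))]
                preds[f] = [
                    bb(
                        g.cx + rng.integers(-6, 7),
                        g.cy + rng.integers(-6, 7),
                        conf=round(float(rng.random()), 2),
                    )
                    for g in gts[f]
                    for _ in range(rng.integers(0, 3))
                ]
            if not any(preds.values()):
                continue
            curve = pr_curve(preds, gts, 0.5)
            for pt in curve:
                tp = fp = fn = 0
                for f in gts:
                    t, p, n = match_frame(preds[f], gts[f], pt.conf_threshold, 0.5)
                    tp, fp, fn = tp + t, fp + p, fn + n
                assert (pt.tp, pt.fp, pt.fn) == (tp, fp, fn)

    def test_no_ground_truth_raises(self):
        with pytest.raises(ValueError):
            pr_curve({0: [bb(1, 1, conf=0.5)]}, {0: []}, 0.5)


class TestAveragePrecision:
    def test_perfect_detector(self):
        assert average_precision([PRPoint(0.5, 10, 0, 0)]) == 1.0

    def test_single_point_precision_1_recall_half(self):
        # 51 of the 101 grid points lie at or below recall 0.5
        assert average_precision([PRPoint(0.5, 1, 0, 1)]) == pytest.approx(51 / 101)

    def test_never_exceeds_max_precision(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n_gt = int(rng.integers(1, 10))
            curve = [
                PRPoint(float(c), int(tp), int(rng.integers(0, 5)), n_gt - int(tp))
                for c, tp in zip(rng.random(5), rng.integers(0, n_gt + 1, 5))
            ]
            assert average_precision(curve) <= max(p.precision for p in curve) + 1e-12

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n_gt = int(rng.integers(1, 8))
            curve = [
                PRPoint(float(c), int(tp), int(fp), n_gt - int(tp))
                for c, tp, fp in zip(
                    rng.random(6), rng.integers(0, n_gt + 1, 6), rng.integers(0, 6, 6)
                )
            ]
            expect = 0.0
            for r in np.linspace(0, 1, 101):
                best = 0.0
                for pt in curve:
                    if pt.recall >= r - 1e-12:
                        best = max(best, pt.precision)
                expect += best / 101
            assert average_precision(curve) == pytest.approx(expect)


class TestMapOver:
    def _three_class_instance(self):
        gts = {
            0: [bb(10, 10, cls="a")],
            1: [bb(10, 10, cls="b")],
            2: [bb(10, 10, cls="c")],
        }
        preds = {
            0: [bb(10, 10, cls="a", conf=0.9)],
            1: [bb(10, 10, cls="b", conf=0.9)],
            2: [
                bb(300, 300, cls="c", conf=0.9),  # miss at high confidence
                bb(10, 10, cls="c", conf=0.5),
            ],
        }
        return preds, gts

    def test_perfect_predictions_map_one(self):
        gts = {0: [bb(10, 10, cls="a"), bb(40, 40, cls="b")]}
        preds = {0: [bb(10, 10, cls="a", conf=0.9), bb(40, 40, cls="b", conf=0.9)]}
        report = map_over(preds, gts, iou_thresholds=(0.5,))
        assert report.map_at[0.5] == 1.0
        assert report.map_mean == 1.0

    def test_class_mean_of_aps(self):
        preds, gts = self._three_class_instance()
        report = map_over(preds, gts, iou_thresholds=(0.5,))
        assert report.ap_per_class["a"][0.5] == 1.0
        assert report.ap_per_class["b"][0.5] == 1.0
        assert report.ap_per_class["c"][0.5] == pytest.approx(0.5)
        assert report.map_at[0.5] == pytest.approx(5 / 6)

    def test_stricter_iou_never_raises_map(self):
        rng = np.random.default_rng(12)
        gts, preds = {}, {}
        for f in range(5):
            gts[f] = [bb(*rng.integers(0, 80, 2), cls="a") for _ in range(2)]
            preds[f] = [
                bb(g.cx + rng.integers(-4, 5), g.cy + rng.integers(-4, 5),
                   cls="a", conf=float(rng.random()))
                for g in gts[f]
            ]
        report = map_over(preds, gts)
        ladder = [report.map_at[t] for t in sorted(report.map_at)]
        assert report.map_mean <= report.map_at[0.5] + 1e-12
        assert all(a >= b - 1e-12 for a, b in zip(ladder, ladder[1:]))

    def test_best_conf_maximizes_f1(self):
        preds, gts = self._three_class_instance()
        report = map_over(preds, gts, iou_thresholds=(0.5,))
        curve = pr_curve(preds, gts, 0.5)
        assert report.f1_at_best == pytest.approx(max(p.f1 for p in curve))


class TestAnnotatorReliability:
    def test_identical_pairs(self):
        pairs = [(bb(1, 1), bb(1, 1))] * 5
        assert annotator_reliability(pairs) == (1.0, 0.0)

    def test_median_of_three(self):
        # IOUs close to {0.9, 0.95, 1.0}: median is the middle value
        def pair_with_iou(t):
            # two unit-height boxes of width 1 overlapping by o: iou = o/(2-o)
            o = 2 * t / (1 + t)
            return (bb(0.5, 0.5, 1.0, 1.0), bb(0.5 + (1 - o), 0.5, 1.0, 1.0))

        pairs = [pair_with_iou(t) for t in (0.9, 0.95, 1.0)]
        med, iqr = annotator_reliability(pairs)
        assert med == pytest.approx(0.95)

    def test_matches_quantile_oracle(self):
        rng = np.random.default_rng(3)
        pairs = []
        for _ in range(40):
            a = bb(*rng.integers(0, 20, 2), *rng.integers(5, 15, 2))
            b = bb(a.cx + rng.integers(-3, 4), a.cy + rng.integers(-3, 4), a.w, a.h)
            pairs.append((a, b))
        med, iqr = annotator_reliability(pairs)
        vals = np.array([iou(a, b) for a, b in pairs])
        assert med == pytest.approx(np.median(vals))
        assert iqr == pytest.approx(
            np.percentile(vals, 75) - np.percentile(vals, 25)
        )


class TestBoxesByFrame:
    def test_round_trip_from_table(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "frame": [0, 0, 2],
                "cls": ["a", "b", "a"],
                "cx": [1.0, 2.0, 3.0],
                "cy": [1.0, 2.0, 3.0],
                "w": [5.0, 5.0, 5.0],
                "h": [5.0, 5.0, 5.0],
                "conf": [0.9, 0.8, 0.7],
            }
        )
        by_frame = boxes_by_frame(df)
        assert sorted(by_frame) == [0, 2]
        assert len(by_frame[0]) == 2
        assert by_frame[2][0].conf == 0.7
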