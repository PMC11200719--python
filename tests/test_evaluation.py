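"""OKS / AP / precision-recall metrics and chew-count error statistics."""

from __future__ import annotations

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chewtrack import (
    OksParams,
    TrajectoryError,
    average_precision,
    count_report,
    error_summary,
    evaluate_keypoints,
    load_coco_keypoints,
    mean_ap,
    oks,
    precision_recall,
    read_manual_counts,
    relative_error,
)


class TestOks:
    def test_exact_match_is_one(self):
        kp = [(10.0, 20.0), (30.0, 40.0)]
        assert oks(kp, kp, OksParams(bbox_area=500.0)) == 1.0

    def test_analytic_exponent_minus_one(self):
        # one visible keypoint with d^2 = 2 * area * sigma^2 gives e^-1
        area, sigma = 400.0, 0.1
        d = math.sqrt(2 * area * sigma ** 2)
        val = oks([(d, 0.0)], [(0.0, 0.0)],
                  OksParams(bbox_area=area, sigmas=(sigma,)))
        assert val == pytest.approx(math.exp(-1), abs=1e-9)

    def test_mean_over_visible_keypoints(self):
        # one perfect keypoint, one effectively at infinity -> mean 0.5
        val = oks([(0.0, 0.0), (1e9, 1e9)], [(0.0, 0.0), (0.0, 0.0)],
                  OksParams(bbox_area=100.0))
        assert val == pytest.approx(0.5)

    def test_invisible_keypoints_excluded(self):
        val = oks([(0.0, 0.0), (1e9, 1e9)], [(0.0, 0.0), (0.0, 0.0)],
                  OksParams(bbox_area=100.0, visibility=(2, 0)))
        assert val == 1.0

    def test_all_invisible_rejected(self):
        with pytest.raises(TrajectoryError):
            oks([(0, 0)], [(0, 0)],
                OksParams(bbox_area=100.0, sigmas=(0.1,), visibility=(0,)))

    def test_strict_as_printed_uses_squared_area(self):
        area, sigma, d = 400.0, 0.1, 10.0
        loose = oks([(d, 0)], [(0, 0)],
                    OksParams(bbox_area=area, sigmas=(sigma,)))
        strict = oks([(d, 0)], [(0, 0)],
                     OksParams(bbox_area=area, sigmas=(sigma,),
                               strict_as_printed=True))
        assert strict == pytest.approx(
            math.exp(-d ** 2 / (2 * area ** 2 * sigma ** 2)))
        assert strict > loose  # larger denominator, milder penalty

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(min_value=0, max_value=5),
           st.floats(min_value=0.1, max_value=5))
    def test_bounded_and_decreasing_in_distance(self, d, extra):
        params = OksParams(bbox_area=200.0, sigmas=(0.1,))
        near = oks([(d, 0)], [(0, 0)], params)
        far = oks([(d + extra, 0)], [(0, 0)], params)
        assert 0.0 <= far < near <= 1.0


class TestAveragePrecision:
    def test_all_exceed(self):
        assert average_precision([0.9, 0.8], 0.5) == 1.0

    def test_none_exceed_either_mode(self):
        assert average_precision([0.3, 0.2], 0.5, "indicator") == 0.0
        assert average_precision([0.3, 0.2], 0.5, "as_printed") == 0.0

    def test_as_printed_averages_surviving_oks(self):
        assert average_precision([0.9, 0.3], 0.5, "as_printed") == pytest.approx(0.45)

    def test_empty_rejected(self):
        with pytest.raises(TrajectoryError):
            average_precision([], 0.5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
           st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    def test_monotone_non_increasing_in_threshold(self, vals, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        for mode in ("indicator", "as_printed"):
            assert average_precision(vals, hi, mode) <= \
                average_precision(vals, lo, mode) + 1e-12


class TestMeanApAndPrecisionRecall:
    @pytest.mark.parametrize("vals,expected",
                             [([1.0, 1.0], 1.0), ([0.0, 1.0], 0.5), ([0.7], 0.7)])
    def test_mean_ap(self, vals, expected):
        assert mean_ap(vals) == pytest.approx(expected)

    def test_precision_recall_arithmetic(self):
        assert precision_recall(9, 1, 3) == pytest.approx((0.9, 0.75))

    def test_empty_prediction_precision_undefined(self):
        p, r = precision_recall(0, 0, 5)
        assert math.isnan(p) and r == 0.0

    def test_perfect_detector(self):
        assert precision_recall(7, 0, 0) == (1.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(TrajectoryError):
            precision_recall(-1, 0, 0)


class TestRelativeError:
    def test_assessed_denominator(self):
        assert relative_error(83, 79) == pytest.approx(4.82, abs=0.005)

    def test_measured_denominator(self):
        assert relative_error(83, 79, "measured") == pytest.approx(5.06, abs=0.005)

    def test_exact_agreement_is_zero(self):
        assert relative_error(100, 100) == 0.0

    def test_swap_symmetry_with_denominator_swap(self):
        assert relative_error(83, 79, "assessed") == \
            relative_error(79, 83, "measured")

    def test_zero_reference_rejected(self):
        with pytest.raises(TrajectoryError):
            relative_error(0, 5)


class TestErrorSummary:
    def test_population_std(self):
        assert error_summary([0.0, 10.0]) == (5.0, 5.0)
        assert error_summary([4.0, 4.0]) == (4.0, 0.0)

    def test_count_report_footer(self, manual_counts_path):
        report = count_report(read_manual_counts(manual_counts_path))
        footer = report[report["video_id"].isin(["mean", "std"])]
        assert footer["relative_error_pct"].tolist() == [5.6, 2.23]


def _coco_doc(instances):
    return {"images": [], "annotations": instances}


def _inst(image_id, kps, area=400.0):
    flat = [c for kp in kps for c in kp]
    return {"image_id": image_id, "keypoints": flat, "area": area}


class TestEvaluateKeypoints:
    SIGMAS = (0.05, 0.05)

    def test_perfect_predictions(self, tmp_path):
        gt_doc = _coco_doc([_inst(1, [(10, 10, 2), (30, 30, 2)]),
                            _inst(2, [(5, 5, 2), (9, 9, 2)])])
        gp, pp = tmp_path / "gt.json", tmp_path / "pred.json"
        gp.write_text(json.dumps(gt_doc))
        pp.write_text(json.dumps(gt_doc))
        res = evaluate_keypoints(load_coco_keypoints(gp), load_coco_keypoints(pp),
                                 sigmas=self.SIGMAS)
        assert res.map_50 == 1.0 and res.map_50_95 == 1.0
        assert res.precision == 1.0 and res.recall == 1.0

    def test_missed_instance_costs_recall_not_precision(self):
        gt = {1: [{"keypoints": np.array([[10., 10., 2], [30., 30., 2]]),
                   "bbox_area": 400.0, "score": 1.0},
                  {"keypoints": np.array([[90., 90., 2], [70., 70., 2]]),
                   "bbox_area": 400.0, "score": 1.0}]}
        pred = {1: [{"keypoints": np.array([[10., 10., 2], [30., 30., 2]]),
                     "bbox_area": 400.0, "score": 1.0}]}
        res = evaluate_keypoints(gt, pred, sigmas=self.SIGMAS)
        assert res.tp == 1 and res.fn == 1 and res.fp == 0
        assert res.precision == 1.0 and res.recall == 0.5

    def test_far_prediction_is_false_positive(self):
        gt = {1: [{"keypoints": np.array([[10., 10., 2], [30., 30., 2]]),
                   "bbox_area": 400.0, "score": 1.0}]}
        pred = {1: [{"keypoints": np.array([[500., 500., 2], [700., 700., 2]]),
                     "bbox_area": 400.0, "score": 1.0}]}
        res = evaluate_keypoints(gt, pred, sigmas=self.SIGMAS)
        assert res.tp == 0 and res.fp == 1 and res.fn == 0
        assert res.map_50 == 0.0

    def test_ap_curve_non_increasing(self):
        rng = np.random.default_rng(17)
        gt, pred = {}, {}
        for i in range(12):
            g = np.array([[50., 50., 2], [80., 80., 2]])
            jitter = rng.normal(0, 3.0, size=(2, 2))
            p = g.copy()
            p[:, :2] += jitter
            gt[i] = [{"keypoints": g, "bbox_area": 900.0, "score": 1.0}]
            pred[i] = [{"keypoints": p, "bbox_area": 900.0, "score": 1.0}]
        res = evaluate_keypoints(gt, pred, sigmas=self.SIGMAS)
        aps = [res.ap_by_threshold[t] for t in sorted(res.ap_by_threshold)]
        assert all(b <= a + 1e-12 for a, b in zip(aps, aps[1:]))

    def test_bbox_fallback_for_area(self, tmp_path):
        doc = _coco_doc([{"image_id": 1, "keypoints": [1, 2, 2, 3, 4, 2],
                          "bbox": [0, 0, 20, 30]}])
        p = tmp_path / "g.json"
        p.write_text(json.dumps(doc))
        loaded = load_coco_keypoints(p)
        assert loaded[1][0]["bbox_area"] == 600.0
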