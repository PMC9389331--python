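"""Matching, P/R/F1 arithmetic, PR curves, AP and stratified rates."""

import numpy as np
import pytest

from helpers import brute_force_ap, brute_force_greedy_match
from tomatodet.decode import DetectionSet
from tomatodet.evaluate import (
    average_precision,
    evaluate_detections,
    f1_score,
    match_detections,
    pr_curve,
    precision_recall_f1,
    round2,
    stratified_rates,
)
from tomatodet.geometry import Circle


def _dets(params):
    return [Circle(x, y, r, score=s) for x, y, r, s in params]


class TestMatching:
    def test_perfect_detections(self):
        gts = [Circle(10, 10, 5), Circle(30, 30, 6)]
        dets = [Circle(10, 10, 5, score=0.9), Circle(30, 30, 6, score=0.8)]
        tp, fp, fn, matches = match_detections(dets, gts, 0.5)
        assert (tp, fp, fn) == (2, 0, 0)
        assert len(matches) == 2

    def test_no_detections(self):
        tp, fp, fn, _ = match_detections([], [Circle(5, 5, 3)] * 0 + [Circle(5, 5, 3)], 0.5)
        assert (tp, fp, fn) == (0, 0, 1)

    def test_each_gt_claimed_at_most_once(self):
        gts = [Circle(10, 10, 5)]
        dets = [Circle(10, 10, 5, score=0.9), Circle(10.5, 10, 5, score=0.8)]
        tp, fp, fn, matches = match_detections(dets, gts, 0.5)
        assert (tp, fp, fn) == (1, 1, 0)
        assert [m[0] for m in matches] == [0]  # higher score wins

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            n_gt, n_det = rng.integers(1, 9), rng.integers(0, 9)
            gts = [Circle(rng.uniform(0, 40), rng.uniform(0, 40), rng.uniform(3, 8))
                   for _ in range(n_gt)]
            dets = [
                Circle(rng.uniform(0, 40), rng.uniform(0, 40), rng.uniform(3, 8),
                       score=float(rng.random()))
                for _ in range(n_det)
            ]
            _, _, _, got = match_detections(dets, gts, 0.3)
            assert sorted(got) == sorted(brute_force_greedy_match(dets, gts, 0.3))

    def test_invariant_tp_plus_fn_is_gt_count(self, rng):
        gts = [Circle(rng.uniform(0, 30), rng.uniform(0, 30), 4) for _ in range(6)]
        dets = [Circle(rng.uniform(0, 30), rng.uniform(0, 30), 4, score=0.5)
                for _ in range(4)]
        tp, fp, fn, _ = match_detections(dets, gts, 0.5)
        assert tp + fn == 6


class TestPrf:
    @pytest.mark.parametrize(
        "r,p,f1",
        [
            (94.30, 95.77, 95.03),  # strongest detector configuration
            (91.56, 92.98, 92.26),  # plain-backbone baseline
            (92.87, 94.32, 93.59),
            (92.98, 94.43, 93.70),
        ],
    )
    def test_f1_reproduces_reported_tables(self, r, p, f1):
        assert round2(f1_score(p, r)) == pytest.approx(f1, abs=0.005)

    def test_f1_equals_p_when_p_equals_r(self):
        assert f1_score(80.0, 80.0) == pytest.approx(80.0)

    def test_counts_to_percentages(self):
        p, r, f1 = precision_recall_f1(8, 2, 2)
        assert p == pytest.approx(80.0)
        assert r == pytest.approx(80.0)
        assert f1 == pytest.approx(80.0)

    def test_degenerate_zero_counts(self):
        assert precision_recall_f1(0, 0, 0) == (0.0, 0.0, 0.0)


class TestPrCurve:
    def test_perfect_detector_single_plateau(self):
        per_image = [(
            _dets([(10, 10, 5, 0.9), (30, 30, 6, 0.8)]),
            [Circle(10, 10, 5), Circle(30, 30, 6)],
        )]
        curve = pr_curve(per_image, 0.5)
        assert curve[-1] == (1.0, 1.0)
        assert all(p == 1.0 for _, p in curve)

    def test_all_wrong_detector(self):
        per_image = [(_dets([(100, 100, 3, 0.9)]), [Circle(10, 10, 5)])]
        curve = pr_curve(per_image, 0.5)
        assert all(p == 0.0 for _, p in curve)

    def test_recall_non_decreasing(self, rng):
        gts = [Circle(rng.uniform(0, 60), rng.uniform(0, 60), 5) for _ in range(8)]
        dets = [Circle(g.cx + rng.normal(0, 3), g.cy + rng.normal(0, 3), 5,
                       score=float(rng.random())) for g in gts for _ in range(2)]
        curve = pr_curve([(dets, gts)], 0.5)
        recalls = [r for r, _ in curve]
        assert recalls == sorted(recalls)

    def test_matches_brute_force_threshold_enumeration(self, rng):
        """Cumulative counts at every distinct score equal an explicit
        re-match of the thresholded subset (greedy in score order)."""
        gts = [Circle(i * 15.0, 10.0, 5.0) for i in range(5)]
        dets = []
        for i in range(5):
            dets.append(Circle(i * 15.0 + rng.normal(0, 1), 10.0, 5.0,
                               score=round(float(rng.random()), 3)))
            dets.append(Circle(rng.uniform(0, 80), 40.0, 5.0,
                               score=round(float(rng.random()), 3)))
        curve = pr_curve([(dets, gts)], 0.3)
        scores = sorted({d.score for d in dets}, reverse=True)
        assert len(curve) == len(scores)
        for (recall, precision), thr in zip(curve, scores):
            subset = [d for d in dets if d.score >= thr]
            matches = brute_force_greedy_match(subset, gts, 0.3)
            tp = len(matches)
            assert recall == pytest.approx(tp / 5)
            assert precision == pytest.approx(tp / len(subset))


class TestAveragePrecision:
    def test_perfect_detector_is_100(self):
        assert average_precision([(1.0, 1.0)]) == pytest.approx(100.0)

    def test_constant_precision_rectangle(self):
        curve = [(0.2, 0.7), (0.5, 0.7), (1.0, 0.7)]
        assert average_precision(curve) == pytest.approx(70.0)

    def test_two_point_hand_value(self):
        assert average_precision([(0.5, 1.0), (1.0, 0.5)]) == pytest.approx(75.0)

    def test_empty_curve(self):
        assert average_precision([]) == 0.0

    def test_duplicate_point_invariance(self):
        curve = [(0.3, 0.9), (0.8, 0.6)]
        assert average_precision(curve) == pytest.approx(
            average_precision(curve + [(0.3, 0.9)])
        )

    def test_matches_brute_force_on_random_curves(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 12))
            recalls = np.sort(rng.random(n))
            precisions = rng.random(n)
            curve = list(zip(recalls.tolist(), precisions.tolist()))
            assert average_precision(curve) == pytest.approx(brute_force_ap(curve), abs=1e-9)

    def test_bounded_in_0_100(self, rng):
        curve = list(zip(np.sort(rng.random(6)).tolist(), rng.random(6).tolist()))
        assert 0.0 <= average_precision(curve) <= 100.0


class TestStratifiedRates:
    def test_reported_lighting_table_rates(self):
        """460/487 correct under direct sun with 22 false detections;
        400/425 correct in shade with 16."""
        gt_labels = ["sunlight"] * 487 + ["shading"] * 425
        gt_matched = [True] * 460 + [False] * 27 + [True] * 400 + [False] * 25
        fp_labels = ["sunlight"] * 22 + ["shading"] * 16
        strata = stratified_rates(gt_labels, gt_matched, fp_labels)
        assert strata["sunlight"]["correct_rate"] == 94.46
        assert strata["sunlight"]["false_rate"] == 4.56
        assert strata["sunlight"]["missed_rate"] == 5.54
        assert strata["shading"]["correct_rate"] == 94.12
        assert strata["shading"]["false_rate"] == 3.85

    def test_reported_occlusion_table_rates(self):
        gt_labels = ["slight"] * 609 + ["severe"] * 303
        gt_matched = [True] * 576 + [False] * 33 + [True] * 284 + [False] * 19
        fp_labels = ["slight"] * 22 + ["severe"] * 16
        strata = stratified_rates(gt_labels, gt_matched, fp_labels)
        assert strata["slight"]["correct_rate"] == 94.58
        assert strata["slight"]["false_rate"] == 3.68
        assert strata["severe"]["correct_rate"] == 93.73
        assert strata["severe"]["false_rate"] == 5.33
        assert strata["severe"]["missed_rate"] == 6.27

    def test_correct_plus_missed_is_100(self, rng):
        gt_labels = [("a" if rng.random() < 0.5 else "b") for _ in range(50)]
        gt_matched = [bool(rng.random() < 0.7) for _ in range(50)]
        strata = stratified_rates(gt_labels, gt_matched, [])
        for tab in strata.values():
            assert 100.0 * tab["tp"] / tab["gt"] + 100.0 * tab["fn"] / tab["gt"] == 100.0

    def test_empty_stratum_absent(self):
        strata = stratified_rates(["a"], [True], ["b"])
        assert "b" not in strata


class TestEvaluateDetections:
    def test_detections_equal_ground_truth(self):
        gts = [Circle(10, 10, 5), Circle(40, 40, 7)]
        dets = DetectionSet([Circle(10, 10, 5, score=0.95), Circle(40, 40, 7, score=0.9)])
        report = evaluate_detections([(dets, gts)])
        assert report.precision == report.recall == report.f1 == report.ap == 100.0

    def test_empty_detections_zero_recall(self):
        report = evaluate_detections([(DetectionSet([]), [Circle(10, 10, 5)])])
        assert report.recall == 0.0 and report.fn == 1

    def test_strata_assembled_from_condition_labels(self):
        gts = [Circle(10, 10, 5), Circle(40, 40, 7)]
        dets = DetectionSet([Circle(10, 10, 5, score=0.95)])
        labels = [[
            {"lighting": "sunlight", "occlusion": "slight"},
            {"lighting": "shading", "occlusion": "severe"},
        ]]
        report = evaluate_detections([(dets, gts)], gt_condition_labels=labels)
        assert report.strata["lighting"]["sunlight"]["correct_rate"] == 100.0
        assert report.strata["lighting"]["shading"]["missed_rate"] == 100.0
        assert report.strata["occlusion"]["severe"]["tp"] == 0
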