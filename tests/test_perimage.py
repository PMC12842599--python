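"""Per-image and dataset mAP tests, including the independent COCO oracle."""

import numpy as np
import pytest

from uweval.det_io import Box, DetectionSet, GroundTruthSet
from uweval.perimage import (
    IOU_THRESHOLDS,
    average_precision,
    dataset_map,
    iou,
    match_image,
    per_image_ap,
    per_image_map5095,
    score_matrix,
)

from _reference_coco import ref_dataset_map, ref_match, ref_per_image_map5095


def B(x, y, w, h):
    return Box(x, y, w, h)


class TestIou:
    def test_identical_boxes(self):
        assert iou(B(0, 0, 10, 10), B(0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(B(0, 0, 10, 10), B(20, 20, 5, 5)) == 0.0

    def test_half_overlap_hand_geometry(self):
        assert iou(B(0, 0, 10, 10), B(5, 0, 10, 10)) == pytest.approx(1 / 3)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            a = B(*rng.uniform(0, 50, 2), *rng.uniform(1, 30, 2))
            b = B(*rng.uniform(0, 50, 2), *rng.uniform(1, 30, 2))
            v = iou(a, b)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(iou(b, a))


class TestMatching:
    def test_single_match(self):
        tp, order, fn = match_image([(B(0, 0, 10, 10), 0.9)], [B(1, 1, 10, 10)], 0.5)
        assert tp.tolist() == [True] and fn == 0

    def test_duplicate_detection_single_assignment(self):
        dets = [(B(0, 0, 10, 10), 0.9), (B(0, 0, 10, 10), 0.8)]
        tp, order, fn = match_image(dets, [B(0, 0, 10, 10)], 0.5)
        assert tp.tolist() == [True, False]

    def test_greedy_rule_matches_brute_force_replay(self, rng):
        # random configurations, including ones where greedy is suboptimal
        for _ in range(30):
            n_gt, n_det = rng.integers(1, 5), rng.integers(0, 6)
            gts = [B(*rng.uniform(0, 40, 2), *rng.uniform(5, 25, 2)) for _ in range(n_gt)]
            dets = [
                (B(*rng.uniform(0, 40, 2), *rng.uniform(5, 25, 2)), float(rng.uniform(0.1, 1)))
                for _ in range(n_det)
            ]
            for thr in (0.3, 0.5):
                tp, order, fn = match_image(dets, gts, thr)
                ref = ref_match(
                    [(d.x, d.y, d.w, d.h, s) for d, s in dets],
                    [(g.x, g.y, g.w, g.h) for g in gts],
                    thr,
                )
                assert tp.tolist() == ref

    def test_greedy_differs_from_optimal_assignment(self):
        # det A (conf 0.9) overlaps both GTs, det B (conf 0.8) only GT1.
        # Greedy gives A->GT1 (higher IoU), leaving B unmatched even though
        # the optimal assignment (A->GT2, B->GT1) would yield two TPs.
        gt1 = B(0, 0, 10, 10)
        gt2 = B(8, 0, 10, 10)
        det_a = (B(2, 0, 10, 10), 0.9)   # IoU 8/12 with gt1, 6/14 with gt2... both >= 0.3
        det_b = (B(0, 0, 10, 11), 0.8)   # overlaps gt1 only
        tp, order, fn = match_image([det_a, det_b], [gt1, gt2], 0.3)
        assert tp.tolist() == [True, False] and fn == 1


class TestAveragePrecision:
    def test_perfect_detections(self):
        assert average_precision(np.array([True, True]), 2) == 1.0

    def test_no_detections(self):
        assert average_precision(np.array([], dtype=bool), 3) == 0.0

    def test_tp_fp_tp_hand_interpolation(self):
        # PR points (1, 0.5), (0.5, 0.5), (2/3, 1); 101-point area:
        # 51 recall points at precision 1, 50 at 2/3
        expected = (51 * 1.0 + 50 * (2 / 3)) / 101
        assert average_precision(np.array([True, False, True]), 2) == pytest.approx(expected)

    def test_appending_lowest_ranked_detection_never_increases_ap(self, rng):
        for _ in range(30):
            tp = rng.random(rng.integers(1, 10)) > 0.4
            n_gt = int(tp.sum() + rng.integers(0, 3) + 1)
            base = average_precision(tp, n_gt)
            appended = average_precision(np.concatenate([tp, [False]]), n_gt)
            assert appended <= base + 1e-12

    def test_undefined_without_ground_truth(self):
        with pytest.raises(ValueError):
            average_precision(np.array([True]), 0)


class TestPerImage:
    def test_identity_detections_score_one(self):
        gts = [(B(0, 0, 10, 10), 1), (B(30, 30, 20, 10), 2)]
        dets = [(box, cat, 1.0) for box, cat in gts]
        score = per_image_map5095(dets, gts, image_id=0, variant_id=0)
        assert score.map5095 == 1.0 and score.defined

    def test_empty_detections_score_zero(self):
        gts = [(B(0, 0, 10, 10), 1)]
        score = per_image_map5095([], gts, 0, 0)
        assert score.map5095 == 0.0

    def test_iou_exactly_060_sweeps_three_thresholds(self):
        # det [0,0,10,6] vs gt [0,0,10,10]: intersection 60, union 100 -> IoU 0.6
        gts = [(B(0, 0, 10, 10), 1)]
        dets = [(B(0, 0, 10, 6), 1, 0.9)]
        score = per_image_map5095(dets, gts, 0, 0)
        assert score.per_threshold[:3] == (1.0, 1.0, 1.0)
        assert all(v == 0.0 for v in score.per_threshold[3:])
        assert score.map5095 == pytest.approx(0.30)

    def test_no_ground_truth_undefined(self):
        score = per_image_map5095([(B(0, 0, 5, 5), 1, 0.9)], [], 0, 0)
        assert not score.defined and np.isnan(score.map5095)

    def test_confidence_rescaling_invariance(self, rng):
        gts = [(B(0, 0, 10, 10), 1), (B(20, 0, 10, 10), 1)]
        dets = [(B(1, 0, 10, 10), 1, 0.8), (B(21, 1, 10, 10), 1, 0.6), (B(40, 40, 5, 5), 1, 0.7)]
        base = per_image_map5095(dets, gts, 0, 0).map5095
        scaled = [(b, c, s * 0.5) for b, c, s in dets]
        assert per_image_map5095(scaled, gts, 0, 0).map5095 == pytest.approx(base)

    def test_map_is_mean_of_thresholds(self, small_scenario):
        ds = small_scenario.detections[1]
        gt = small_scenario.ground_truth
        for image_id in gt.image_ids[:5]:
            score = per_image_map5095(ds.for_image(image_id), gt.boxes[image_id], image_id, 1)
            if score.defined:
                assert score.map5095 == pytest.approx(np.mean(score.per_threshold))


def _random_fixture(rng, n_images=20, n_categories=2):
    gts = {}
    dets = {}
    for image_id in range(n_images):
        n_gt = int(rng.integers(0, 5))
        gts[image_id] = [
            (B(*rng.uniform(0, 80, 2), *rng.uniform(8, 40, 2)), int(rng.integers(1, n_categories + 1)))
            for _ in range(n_gt)
        ]
        image_dets = []
        for box, cat in gts[image_id]:
            if rng.random() < 0.75:
                image_dets.append(
                    (B(box.x + rng.normal(0, 3), box.y + rng.normal(0, 3),
                       max(box.w + rng.normal(0, 3), 2), max(box.h + rng.normal(0, 3), 2)),
                     cat, float(rng.uniform(0.2, 1.0)))
                )
        for _ in range(int(rng.integers(0, 3))):
            image_dets.append(
                (B(*rng.uniform(0, 80, 2), *rng.uniform(8, 30, 2)),
                 int(rng.integers(1, n_categories + 1)), float(rng.uniform(0.05, 0.9)))
            )
        if image_dets:
            dets[image_id] = image_dets
    gt_set = GroundTruthSet(boxes=gts, categories={c: f"c{c}" for c in range(1, n_categories + 1)})
    det_set = DetectionSet(variant_id=0, detections=dets)
    return gt_set, det_set


class TestAgainstReferenceProtocol:
    def test_per_image_scores_match_reference(self, rng):
        gt_set, det_set = _random_fixture(rng)
        for image_id in gt_set.image_ids:
            score = per_image_map5095(det_set.for_image(image_id), gt_set.boxes[image_id], image_id, 0)
            ref = ref_per_image_map5095(
                [(b.x, b.y, b.w, b.h, c, s) for b, c, s in det_set.for_image(image_id)],
                [(b.x, b.y, b.w, b.h, c) for b, c in gt_set.boxes[image_id]],
            )
            if ref is None:
                assert not score.defined
            else:
                assert score.map5095 == pytest.approx(ref, abs=1e-6)

    def test_dataset_map_matches_reference(self, rng):
        gt_set, det_set = _random_fixture(rng)
        result = dataset_map(det_set, gt_set)
        ref50, ref5095 = ref_dataset_map(
            {i: [(b.x, b.y, b.w, b.h, c, s) for b, c, s in det_set.for_image(i)] for i in gt_set.image_ids},
            {i: [(b.x, b.y, b.w, b.h, c) for b, c in gt_set.boxes[i]] for i in gt_set.image_ids},
        )
        assert result["map50"] == pytest.approx(ref50, abs=1e-6)
        assert result["map5095"] == pytest.approx(ref5095, abs=1e-6)

    def test_perfect_and_empty_dataset_map(self):
        gts = {0: [(B(0, 0, 10, 10), 1)], 1: [(B(5, 5, 8, 8), 1)]}
        gt_set = GroundTruthSet(boxes=gts, categories={1: "c1"})
        perfect = DetectionSet(0, {i: [(b, c, 1.0) for b, c in v] for i, v in gts.items()})
        assert dataset_map(perfect, gt_set)["map5095"] == 1.0
        empty = DetectionSet(0, {})
        assert dataset_map(empty, gt_set)["map5095"] == 0.0

    def test_single_image_dataset_equals_per_image(self, rng):
        for _ in range(5):
            gt_set, det_set = _random_fixture(rng, n_images=1)
            if not gt_set.boxes[0]:
                continue
            score = per_image_map5095(det_set.for_image(0), gt_set.boxes[0], 0, 0)
            assert dataset_map(det_set, gt_set)["map5095"] == pytest.approx(score.map5095, abs=1e-12)


class TestScoreMatrix:
    def test_single_variant_single_column(self, small_scenario):
        matrix = score_matrix(small_scenario.detections[:1], small_scenario.ground_truth)
        assert matrix.values.shape[1] == 1

    def test_duplicated_variant_gives_identical_columns(self, small_scenario):
        from dataclasses import replace

        ds = small_scenario.detections[1]
        dup = replace(ds, variant_id=99)
        matrix = score_matrix([ds, dup], small_scenario.ground_truth)
        a, b = matrix.values[ds.variant_id], matrix.values[99]
        assert a.equals(b)

    def test_matrix_matches_elementwise_recomputation(self, small_scenario):
        matrix = score_matrix(small_scenario.detections, small_scenario.ground_truth)
        gt = small_scenario.ground_truth
        for ds in small_scenario.detections[:2]:
            for image_id in gt.image_ids[:10]:
                expected = per_image_map5095(ds.for_image(image_id), gt.boxes[image_id], image_id, ds.variant_id)
                got = matrix.values.at[image_id, ds.variant_id]
                if expected.defined:
                    assert got == pytest.approx(expected.map5095)
                else:
                    assert np.isnan(got)

    def test_duplicate_variant_ids_rejected(self, small_scenario):
        with pytest.raises(ValueError, match="duplicate"):
            score_matrix([small_scenario.detections[0]] * 2, small_scenario.ground_truth)

    def test_all_scores_in_unit_interval(self, small_scenario):
        matrix = score_matrix(small_scenario.detections, small_scenario.ground_truth)
        vals = matrix.values.to_numpy()
        finite = vals[~np.isnan(vals)]
        assert ((0.0 <= finite) & (finite <= 1.0)).all()
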