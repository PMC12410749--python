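"""Evaluation metrics against hand-computed values and exhaustive oracles."""

from itertools import permutations

import numpy as np
import pytest

from allinsam.metrics import (
    aggregated_jaccard,
    best_f1_and_pr,
    dice_coefficient,
    evaluate_image,
    instance_f1,
    iou_score,
    pixel_auc,
    _pairwise_iou,
)
from allinsam.types import InstanceMask


def disk_map(centers_radii, shape=(32, 32)):
    lab = np.zeros(shape, dtype=np.int32)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, (r, c, rad) in enumerate(centers_radii, start=1):
        lab[((rr - r) ** 2 + (cc - c) ** 2) <= rad**2] = i
    ids = [int(i) for i in np.unique(lab) if i > 0]
    return InstanceMask(lab, {i: 1 for i in ids})


class TestPixelMetrics:
    def test_dice_identical(self):
        m = np.eye(5)
        assert dice_coefficient(m, m) == 1.0

    def test_dice_disjoint(self):
        a = np.zeros((4, 4))
        a[0, 0] = 1
        b = np.zeros((4, 4))
        b[3, 3] = 1
        assert dice_coefficient(a, b) == 0.0

    def test_dice_hand_count(self):
        a = np.zeros((4, 4))
        a[0, 0] = a[0, 1] = 1
        b = np.zeros((4, 4))
        b[0, 1] = b[0, 2] = 1
        assert dice_coefficient(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3))
        assert dice_coefficient(z, z) == 1.0
        assert iou_score(z, z) == 1.0

    def test_iou_hand_count(self):
        a = np.zeros((4, 4))
        a[0, :2] = 1
        b = np.zeros((4, 4))
        b[0, 1:3] = 1
        assert iou_score(a, b) == pytest.approx(1.0 / 3.0)


class TestInstanceF1:
    def test_identical_maps(self):
        m = disk_map([(8, 8, 4), (20, 20, 5)])
        assert instance_f1(m, m) == 1.0

    def test_empty_prediction(self):
        empty = InstanceMask(np.zeros((32, 32), dtype=np.int32), {})
        truth = disk_map([(8, 8, 4)])
        assert instance_f1(empty, truth) == 0.0

    def test_one_displaced_instance_hand_value(self):
        truth = disk_map([(6, 6, 3), (16, 16, 3), (26, 26, 3)])
        pred = disk_map([(6, 6, 3), (16, 16, 3), (26, 6, 3)])  # third displaced
        assert instance_f1(pred, truth) == pytest.approx(2 * 2 / (2 * 2 + 1 + 1))

    def test_matches_exhaustive_assignment(self):
        def oracle(pred, truth, thr=0.5):
            p_ids, t_ids, iou = _pairwise_iou(pred, truth)
            if not p_ids and not t_ids:
                return 1.0
            best_tp = 0
            if p_ids and t_ids:
                if len(p_ids) <= len(t_ids):
                    small, big, mat = range(len(p_ids)), range(len(t_ids)), iou
                else:
                    small, big, mat = range(len(t_ids)), range(len(p_ids)), iou.T
                for perm in permutations(big, len(list(small))):
                    tp = sum(1 for i, j in zip(small, perm) if mat[i, j] >= thr)
                    best_tp = max(best_tp, tp)
            fp, fn = len(p_ids) - best_tp, len(t_ids) - best_tp
            return 2 * best_tp / (2 * best_tp + fp + fn) if (best_tp + fp + fn) else 1.0

        rng = np.random.default_rng(42)
        for _ in range(200):
            maps = []
            for _ in range(2):
                n = rng.integers(0, 6)
                maps.append(
                    disk_map(
                        [
                            (rng.integers(4, 28), rng.integers(4, 28), rng.integers(2, 6))
                            for _ in range(n)
                        ]
                    )
                )
            assert instance_f1(maps[0], maps[1]) == pytest.approx(oracle(*maps))


class TestAggregatedJaccard:
    def test_identical_maps(self):
        m = disk_map([(8, 8, 4), (20, 20, 5)])
        assert aggregated_jaccard(m, m) == 1.0

    def test_spurious_instance_hand_accumulation(self):
        # truth: one 100-px instance; pred: same plus a 10-px spurious blob
        truth_lab = np.zeros((40, 40), dtype=np.int32)
        truth_lab[0:10, 0:10] = 1  # 100 px
        pred_lab = truth_lab.copy()
        pred_lab[30:35, 30:32] = 2  # 10 px spurious
        truth = InstanceMask(truth_lab, {1: 1})
        pred = InstanceMask(pred_lab, {1: 1, 2: 1})
        assert aggregated_jaccard(pred, truth) == pytest.approx(100 / 110)

    def test_never_exceeds_pixel_iou(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            maps = []
            for _ in range(2):
                n = rng.integers(1, 5)
                maps.append(
                    disk_map(
                        [
                            (rng.integers(4, 28), rng.integers(4, 28), rng.integers(2, 6))
                            for _ in range(n)
                        ]
                    )
                )
            aji = aggregated_jaccard(maps[0], maps[1])
            iou = iou_score(maps[0].labels > 0, maps[1].labels > 0)
            assert aji <= iou + 1e-12


class TestThresholdFreeMetrics:
    def test_auc_perfect_separation(self):
        truth = np.array([[1, 1, 0, 0]])
        prob = np.array([[0.9, 0.8, 0.2, 0.1]])
        assert pixel_auc(prob, truth) == 1.0

    def test_auc_constant_scores(self):
        truth = np.array([[1, 0, 1, 0]])
        prob = np.full((1, 4), 0.5)
        assert pixel_auc(prob, truth) == pytest.approx(0.5)

    def test_auc_four_pixel_toy(self):
        truth = np.array([[1, 0, 1, 0]])
        prob = np.array([[0.9, 0.8, 0.4, 0.1]])
        # pair enumeration: of 4 positive-negative pairs, 3 correctly ordered
        assert pixel_auc(prob, truth) == pytest.approx(0.75)

    def test_auc_single_class_truth_nan(self):
        assert np.isnan(pixel_auc(np.random.rand(2, 2), np.ones((2, 2))))

    def test_best_f1_perfect(self):
        truth = np.array([[1, 0], [0, 1]])
        best, rec, prec = best_f1_and_pr(truth.astype(float), truth)
        assert (best, rec, prec) == (1.0, 1.0, 1.0)

    def test_best_f1_dominates_threshold_half(self):
        rng = np.random.default_rng(2)
        prob = rng.random((8, 8))
        truth = (rng.random((8, 8)) < 0.4).astype(int)
        best, rec, prec = best_f1_and_pr(prob, truth)
        f1_half = 0.0
        if prec + rec > 0:
            f1_half = 2 * prec * rec / (prec + rec)
        assert best >= f1_half - 1e-12

    def test_best_f1_four_pixel_toy_exhaustive(self):
        truth = np.array([[1, 0, 1, 0]])
        prob = np.array([[0.9, 0.8, 0.4, 0.1]])
        # exhaustive sweep oracle over all distinct thresholds
        scores = sorted(set(prob.ravel())) + [2.0]
        best_oracle = 0.0
        for t in scores:
            hard = prob >= t
            tp = int((hard & (truth == 1)).sum())
            fp = int((hard & (truth == 0)).sum())
            fn = int((~hard & (truth == 1)).sum())
            if tp:
                p, r = tp / (tp + fp), tp / (tp + fn)
                best_oracle = max(best_oracle, 2 * p * r / (p + r))
        best, _, _ = best_f1_and_pr(prob, truth)
        assert best == pytest.approx(best_oracle)
        assert best == pytest.approx(0.8)

    def test_empty_truth_recall_nan(self):
        best, rec, prec = best_f1_and_pr(np.zeros((2, 2)), np.zeros((2, 2)))
        assert np.isnan(rec)
        assert prec == 1.0


class TestMonotonicity:
    def test_erosion_never_improves_overlap_metrics(self):
        from scipy import ndimage as ndi

        truth_lab = np.zeros((48, 48), dtype=np.int32)
        rr, cc = np.mgrid[0:48, 0:48]
        truth_lab[((rr - 24) ** 2 + (cc - 24) ** 2) <= 144] = 1
        truth = InstanceMask(truth_lab, {1: 1})
        prev = (1.0, 1.0, 1.0)
        mask = truth_lab > 0
        for _ in range(5):
            pred = InstanceMask(mask.astype(np.int32), {1: 1} if mask.any() else {})
            d = dice_coefficient(mask, truth_lab > 0)
            i = iou_score(mask, truth_lab > 0)
            a = aggregated_jaccard(pred, truth)
            assert (d, i, a) <= prev
            prev = (d, i, a)
            mask = ndi.binary_erosion(mask, iterations=2)


class TestEvaluateImage:
    def test_full_report_on_perfect_prediction(self, patch_clean):
        _, inst = patch_clean
        probs = {c: inst.class_mask(c).astype(float) for c in (1, 2)}
        truth = {c: inst.class_mask(c).astype(np.uint8) for c in (1, 2)}
        report = evaluate_image(probs, truth, inst)
        assert report.dice == pytest.approx(1.0)
        assert report.iou == pytest.approx(1.0)
        assert report.instance_f1 == pytest.approx(1.0)
        assert report.aji == pytest.approx(1.0)
        row = report.to_csv_row()
        assert len(row.split(",")) == len(report.csv_header().split(","))
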