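import itertools

import numpy as np
import pytest

from nucsplit3d import (
    LabelVolume,
    aji,
    detection_metrics,
    evaluate,
    instance_iou_matrix,
    match_at_threshold,
)


def shifted_cube_pair():
    """2x2x2 GT cube vs the same cube shifted +1 in x: IoU = 4/12 = 1/3."""
    gt = np.zeros((6, 6, 6), dtype=np.int32)
    gt[1:3, 1:3, 1:3] = 1
    pred = np.zeros_like(gt)
    pred[2:4, 1:3, 1:3] = 1
    return LabelVolume(gt), LabelVolume(pred)


def brute_force_best_matching(gt, pred, t):
    """Exhaustive optimal one-to-one matching (oracle for small volumes)."""
    gt_ids = list(gt.labels())
    pred_ids = list(pred.labels())
    iou = {}
    for g in gt_ids:
        for p in pred_ids:
            inter = np.sum((gt.data == g) & (pred.data == p))
            union = np.sum((gt.data == g) | (pred.data == p))
            if inter:
                iou[(g, p)] = inter / union
    best = 0
    k = min(len(gt_ids), len(pred_ids))
    for r in range(k, 0, -1):
        for gs in itertools.permutations(gt_ids, r):
            for ps in itertools.combinations(pred_ids, r):
                if all(iou.get((g, p), 0) >= t for g, p in zip(gs, ps)):
                    best = max(best, r)
            if best == r:
                break
        if best:
            break
    return best


class TestIoUMatrix:
    def test_identity_with_permuted_labels(self, small_labels):
        perm = np.zeros_like(small_labels.data)
        ids = small_labels.labels()
        for i, k in enumerate(ids):
            perm[small_labels.data == k] = ids[(i + 1) % ids.size]
        m = instance_iou_matrix(small_labels, LabelVolume(perm))
        coo = m.tocoo()
        ones = coo.data > 1 - 1e-12
        assert ones.sum() == ids.size
        assert np.unique(coo.row[ones]).size == ids.size

    def test_shifted_cube_value(self):
        gt, pred = shifted_cube_pair()
        m = instance_iou_matrix(gt, pred)
        assert m[1, 1] == pytest.approx(1 / 3)

    def test_disjoint_volumes_empty(self):
        gt, _ = shifted_cube_pair()
        far = np.zeros_like(gt.data)
        far[4:, 4:, 4:] = 1
        m = instance_iou_matrix(gt, LabelVolume(far))
        assert m.nnz == 0


class TestMatching:
    def test_shifted_cube_across_thresholds(self):
        gt, pred = shifted_cube_pair()
        m = instance_iou_matrix(gt, pred)
        low = match_at_threshold(m, 0.25, n_gt=1, n_pred=1)
        assert (low.n_tp, low.n_fp, low.n_fn) == (1, 0, 0)
        high = match_at_threshold(m, 0.5, n_gt=1, n_pred=1)
        assert (high.n_tp, high.n_fp, high.n_fn) == (0, 1, 1)

    def test_one_to_one_rule(self):
        # two predictions over one GT object: exactly one TP, one FP
        gt = np.zeros((6, 6, 6), dtype=np.int32)
        gt[1:5, 1:5, 1:5] = 1
        pred = np.zeros_like(gt)
        pred[1:5, 1:3, 1:5] = 1
        pred[1:5, 3:5, 1:5] = 2
        m = instance_iou_matrix(LabelVolume(gt), LabelVolume(pred))
        res = match_at_threshold(m, 0.25, n_gt=1, n_pred=2)
        assert (res.n_tp, res.n_fp, res.n_fn) == (1, 1, 0)

    def test_greedy_equals_optimal_on_small_fixtures(self, rng):
        # random <= 6-instance volumes: greedy matching cardinality equals
        # the exhaustive optimal assignment at every threshold
        for seed in range(8):
            r = np.random.default_rng(seed)
            gt = np.zeros((12, 12, 12), dtype=np.int32)
            pred = np.zeros_like(gt)
            for k in range(1, r.integers(2, 7)):
                c = r.integers(2, 10, 3)
                gt[c[0] - 2 : c[0] + 2, c[1] - 2 : c[1] + 2, c[2] - 2 : c[2] + 2] = k
                o = c + r.integers(-2, 3, 3)
                o = np.clip(o, 2, 10)
                pred[o[0] - 2 : o[0] + 2, o[1] - 2 : o[1] + 2, o[2] - 2 : o[2] + 2] = k
            gtv, predv = LabelVolume(gt), LabelVolume(pred)
            m = instance_iou_matrix(gtv, predv)
            for t in (0.25, 0.4, 0.6):
                greedy = match_at_threshold(m, t, n_gt=gtv.labels().size,
                                            n_pred=predv.labels().size)
                assert greedy.n_tp == brute_force_best_matching(gtv, predv, t)


class TestDetectionMetrics:
    def test_perfect_prediction_scores_100(self, small_labels):
        rep = evaluate(small_labels, small_labels)
        assert rep.mean_precision == rep.mean_recall == rep.mean_f1 == 100.0
        assert rep.mean_ap == 100.0
        assert rep.aji == pytest.approx(1.0)

    def test_empty_prediction(self, small_labels):
        empty = LabelVolume(np.zeros(small_labels.shape, dtype=np.int32))
        rep = detection_metrics(small_labels, empty)
        assert rep.mean_precision == rep.mean_recall == rep.mean_f1 == 0.0

    def test_counts_to_metrics_closed_form(self):
        # 10 GT, 8 matched, 1 spurious: P=8/9, R=8/10, F1=16/19 at every t
        gt = np.zeros((40, 12, 12), dtype=np.int32)
        pred = np.zeros_like(gt)
        for k in range(10):
            gt[4 * k : 4 * k + 3, 2:5, 2:5] = k + 1
            if k < 8:
                pred[4 * k : 4 * k + 3, 2:5, 2:5] = k + 1
        pred[1:3, 8:11, 8:11] = 99  # spurious detection
        rep = detection_metrics(LabelVolume(gt), LabelVolume(pred))
        assert rep.mean_precision == pytest.approx(100 * 8 / 9)
        assert rep.mean_recall == pytest.approx(100 * 8 / 10)
        assert rep.mean_f1 == pytest.approx(100 * 16 / 19)
        assert rep.mean_ap == pytest.approx(100 * 8 / 11)

    def test_relabeling_invariance(self, small_labels, rng):
        ids = small_labels.labels()
        perm = rng.permutation(ids.size) + 1
        lut = np.zeros(ids.max() + 1, dtype=np.int32)
        lut[ids] = perm
        relabeled = LabelVolume(lut[small_labels.data])
        a = evaluate(small_labels, small_labels)
        b = evaluate(small_labels, relabeled)
        assert a.mean_ap == b.mean_ap
        assert a.aji == pytest.approx(b.aji)


class TestCurveAP:
    def test_perfect_single_detection(self):
        gt, pred = shifted_cube_pair()
        from nucsplit3d.metrics import ap_from_scores

        assert ap_from_scores(gt, pred, {1: 0.9}, 0.25) == pytest.approx(100.0)
        assert ap_from_scores(gt, pred, {1: 0.9}, 0.5) == 0.0

    def test_high_confidence_false_positive_halves_ap(self):
        # FP ranked above the TP: PR curve reaches precision 1/2 at recall 1
        gt = np.zeros((10, 6, 6), dtype=np.int32)
        gt[1:4, 1:4, 1:4] = 1
        pred = np.zeros_like(gt)
        pred[1:4, 1:4, 1:4] = 2       # matches, low confidence
        pred[6:9, 1:4, 1:4] = 1       # spurious, high confidence
        from nucsplit3d.metrics import ap_from_scores

        ap = ap_from_scores(LabelVolume(gt), LabelVolume(pred),
                            {1: 0.9, 2: 0.3}, 0.5)
        assert ap == pytest.approx(50.0)

    def test_missing_scores_rejected(self):
        gt, pred = shifted_cube_pair()
        from nucsplit3d.metrics import ap_from_scores

        with pytest.raises(ValueError, match="missing confidence"):
            ap_from_scores(gt, pred, {}, 0.25)


class TestAJI:
    def test_identity_is_one(self, small_labels):
        assert aji(small_labels, small_labels) == pytest.approx(1.0)

    def test_empty_prediction_is_zero(self, small_labels):
        empty = LabelVolume(np.zeros(small_labels.shape, dtype=np.int32))
        assert aji(small_labels, empty) == 0.0

    def test_shifted_cube_value(self):
        gt, pred = shifted_cube_pair()
        assert aji(gt, pred) == pytest.approx(1 / 3)

    def test_bounded_in_unit_interval(self, small_labels, rng):
        noisy = LabelVolume((rng.random(small_labels.shape) > 0.7).astype(int))
        v = aji(small_labels, noisy)
        assert 0.0 <= v <= 1.0
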