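from itertools import permutations

import numpy as np
import pytest

from calunmix.datatypes import NeuronMasks, Transient
from calunmix.evaluate import (
    grid_search_cv,
    iou,
    match_masks,
    match_transients,
    pooled_video_scores,
    precision_recall_f1,
    score_transients,
    transient_distance_matrix,
)


def tr(s, e):
    return Transient(s, e, (s + e) // 2)


class TestDistanceMatrix:
    def test_disjoint_zero(self):
        D = transient_distance_matrix([tr(0, 5)], [tr(10, 15)])
        assert D[0, 0] == 0

    def test_identical_counts_frames(self):
        D = transient_distance_matrix([tr(3, 9)], [tr(3, 9)])
        assert D[0, 0] == -7

    def test_partial_overlap(self):
        D = transient_distance_matrix([tr(3, 10)], [tr(8, 12)])
        assert D[0, 0] == -3  # frames 8, 9, 10


class TestMatchTransients:
    def test_identical_sets_all_matched(self):
        A = [tr(0, 5), tr(20, 30), tr(50, 55)]
        assert len(match_transients(A, list(A))) == 3

    def test_disjoint_sets_no_matches(self):
        assert match_transients([tr(0, 5)], [tr(100, 105)]) == []

    def test_matches_brute_force_enumeration(self, rng):
        # zero-padding to a square matrix makes exhaustive enumeration
        # over permutations equivalent to the rectangular assignment
        for _ in range(100):
            nA, nB = (int(v) for v in rng.integers(1, 7, 2))
            A = [tr(int(s), int(s + rng.integers(1, 15))) for s in rng.integers(0, 80, nA)]
            B = [tr(int(s), int(s + rng.integers(1, 15))) for s in rng.integers(0, 80, nB)]
            D = transient_distance_matrix(A, B)
            n = max(nA, nB)
            Dp = np.zeros((n, n))
            Dp[:nA, :nB] = D
            best = min(
                sum(Dp[i, p[i]] for i in range(n)) for p in permutations(range(n))
            )
            pairs = match_transients(A, B)
            total = sum(D[r, c] for r, c in pairs)
            assert total == best
            assert all(D[r, c] < 0 for r, c in pairs)


class TestScores:
    def test_perfect_agreement(self):
        s = precision_recall_f1(10, 10, 10)
        assert s.f1 == 1.0

    def test_harmonic_mean_formula(self):
        s = precision_recall_f1(5, 5, 10)  # precision 1, recall 0.5
        assert s.f1 == pytest.approx(2 / 3)

    def test_zero_tp_zero_f1(self):
        assert precision_recall_f1(0, 5, 5).f1 == 0.0

    def test_both_empty_flagged_perfect(self):
        s = precision_recall_f1(0, 0, 0)
        assert s.f1 == 1.0 and s.degenerate

    def test_symmetry_swaps_precision_recall(self):
        A = [tr(0, 5), tr(20, 30)]
        B = [tr(2, 6), tr(40, 45), tr(60, 66)]
        ab = score_transients(A, B)
        ba = score_transients(B, A)
        assert ab.precision == ba.recall and ab.recall == ba.precision
        assert ab.f1 == pytest.approx(ba.f1)

    def test_pooled_counts_sum_before_ratios(self):
        det = [[tr(0, 5)], [tr(10, 15), tr(30, 35)]]
        gt = [[tr(0, 5)], [tr(50, 55)]]
        s = pooled_video_scores(det, gt)
        assert (s.tp, s.n_detected, s.n_gt) == (1, 3, 2)


class TestMaskMatching:
    def test_iou_identical(self):
        m = np.zeros((5, 5), bool); m[1:3, 1:3] = True
        assert iou(m, m) == 1.0

    def test_iou_disjoint(self):
        a = np.zeros((5, 5), bool); a[0, 0] = True
        b = np.zeros((5, 5), bool); b[4, 4] = True
        assert iou(a, b) == 0.0

    def test_iou_two_pixel_masks_sharing_one(self):
        a = np.zeros((5, 5), bool); a[0, 0] = a[0, 1] = True
        b = np.zeros((5, 5), bool); b[0, 1] = b[0, 2] = True
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_identical_sets_fully_matched(self, two_disk_masks):
        mm = match_masks(two_disk_masks, two_disk_masks)
        assert sorted(mm.pairs) == [(0, 0), (1, 1)]
        assert mm.unmatched_a == [] and mm.unmatched_b == []

    def test_iou_above_half_matches_below_does_not(self):
        base = np.zeros((10, 10), bool); base[2:8, 2:8] = True  # 36 px
        shifted_ok = np.roll(base, 1, axis=1)    # IoU 30/42 ~ 0.71
        shifted_bad = np.roll(base, 4, axis=1)   # IoU 12/60 = 0.2
        ok = match_masks(NeuronMasks(base[None]), NeuronMasks(shifted_ok[None]))
        bad = match_masks(NeuronMasks(base[None]), NeuronMasks(shifted_bad[None]))
        assert ok.pairs == [(0, 0)]
        assert bad.pairs == []

    def test_symmetric_in_arguments(self, rng):
        from calunmix.synthdata import _disk_mask

        for _ in range(25):
            def random_set(n):
                ms = [
                    _disk_mask(tuple(rng.uniform(3, 13, 2)), rng.uniform(2, 4), 16, 16)
                    for _ in range(n)
                ]
                return NeuronMasks(np.stack(ms))

            A, B = random_set(3), random_set(2)
            ab = match_masks(A, B)
            ba = match_masks(B, A)
            assert sorted((b, a) for a, b in ab.pairs) == sorted(ba.pairs)


class TestCrossValidation:
    def test_single_point_grid_forced(self):
        scores = np.array([[[0.8]], [[0.6]], [[0.9]]])
        folds, mean = grid_search_cv(scores, [4.0], [1.0])
        assert [f.test_f1 for f in folds] == [0.8, 0.6, 0.9]
        assert mean == pytest.approx(np.mean([0.8, 0.6, 0.9]))

    def test_dominant_point_always_chosen(self, rng):
        n_v, n_t, n_a = 4, 3, 3
        scores = rng.uniform(0, 0.5, (n_v, n_t, n_a))
        scores[:, 1, 2] = 0.95  # strictly dominates for every video
        folds, _ = grid_search_cv(scores, [3.0, 4.0, 5.0], [0.5, 1.0, 2.0])
        for f in folds:
            assert (f.th_snr, f.alpha) == (4.0, 2.0)

    def test_each_video_tested_once(self, rng):
        scores = rng.uniform(size=(5, 2, 2))
        folds, _ = grid_search_cv(scores, [3.0, 4.0], [0.5, 1.0])
        assert sorted(f.test_video for f in folds) == [0, 1, 2, 3, 4]

    def test_tie_breaks_to_smaller_alpha_then_th(self):
        scores = np.full((3, 2, 2), 0.5)
        folds, _ = grid_search_cv(scores, [4.0, 3.0], [2.0, 1.0])
        for f in folds:
            assert (f.alpha, f.th_snr) == (1.0, 3.0)

    def test_too_few_videos_rejected(self):
        with pytest.raises(ValueError):
            grid_search_cv(np.ones((1, 1, 1)), [1.0], [1.0])
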