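"""Scoring of detected transients and mask sets.

Detected and ground-truth transients are matched one-to-one with the
Hungarian algorithm on a distance of minus the number of overlapping
frames; matched pairs with at least one shared frame are true positives,
and precision/recall/F1 follow.  Neuron mask sets are matched the same
way on Dist = 1 − IoU (IoU ≥ 0.5) or 2 (unmatchable).  Leave-one-out
cross-validation selects th_SNR and α on training videos and reports the
held-out F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datatypes import EvalScores, MaskMatch, NeuronMasks, Transient

__all__ = [
    "transient_distance_matrix",
    "match_transients",
    "precision_recall_f1",
    "score_transients",
    "pooled_video_scores",
    "iou",
    "match_masks",
    "grid_search_cv",
    "FoldResult",
]

_UNMATCHABLE_DIST = 2.0


def transient_distance_matrix(
    A: list[Transient], B: list[Transient]
) -> np.ndarray:
    """D[a, b] = −(number of frames shared by a and b), inclusive ranges."""
    D = np.zeros((len(A), len(B)))
    for ia, a in enumerate(A):
        for ib, b in enumerate(B):
            overlap = min(a.end_frame, b.end_frame) - max(a.start_frame, b.start_frame) + 1
            D[ia, ib] = -max(0, overlap)
    return D


def match_transients(
    A: list[Transient], B: list[Transient]
) -> list[tuple[int, int]]:
    """Hungarian assignment on the overlap distance; pairs with zero
    overlap are discarded.  Returns (index in A, index in B) pairs."""
    if not A or not B:
        return []
    D = transient_distance_matrix(A, B)
    rows, cols = linear_sum_assignment(D)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if D[r, c] < 0]


def precision_recall_f1(tp: int, n_detected: int, n_gt: int) -> EvalScores:
    """Precision = tp/n_detected, recall = tp/n_gt, F1 the harmonic mean.

    Empty-vs-empty comparisons score 1 (perfect agreement on nothing)
    and are flagged ``degenerate``; tp = 0 against any non-empty side
    scores 0.
    """
    if tp > min(n_detected, n_gt):
        raise ValueError("tp cannot exceed either set size")
    if n_detected == 0 and n_gt == 0:
        return EvalScores(1.0, 1.0, 1.0, 0, 0, 0, degenerate=True)
    precision = tp / n_detected if n_detected else 0.0
    recall = tp / n_gt if n_gt else 0.0
    if tp == 0:
        return EvalScores(precision, recall, 0.0, tp, n_detected, n_gt)
    f1 = 2.0 / (1.0 / recall + 1.0 / precision)
    return EvalScores(precision, recall, f1, tp, n_detected, n_gt)


def score_transients(detected: list[Transient], gt: list[Transient]) -> EvalScores:
    """Match one detected set against one ground-truth set and score."""
    tp = len(match_transients(detected, gt))
    return EvalScores(**vars(precision_recall_f1(tp, len(detected), len(gt))))


def pooled_video_scores(
    detected_per_neuron: list[list[Transient]],
    gt_per_neuron: list[list[Transient]],
) -> EvalScores:
    """Video-level scores: counts are pooled over neurons before the
    ratios are formed (matching is still per neuron)."""
    if len(detected_per_neuron) != len(gt_per_neuron):
        raise ValueError("per-neuron lists must align")
    tp = nd = ng = 0
    for det, gt in zip(detected_per_neuron, gt_per_neuron):
        tp += len(match_transients(det, gt))
        nd += len(det)
        ng += len(gt)
    return precision_recall_f1(tp, nd, ng)


def iou(m1: np.ndarray, m2: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    m1 = np.asarray(m1, dtype=bool)
    m2 = np.asarray(m2, dtype=bool)
    union = np.count_nonzero(m1 | m2)
    if union == 0:
        raise ValueError("both masks are empty")
    return np.count_nonzero(m1 & m2) / union


def match_masks(A: NeuronMasks, B: NeuronMasks) -> MaskMatch:
    """One-to-one mask pairing: Dist = 1 − IoU when IoU ≥ 0.5, else 2
    (unmatchable); Hungarian assignment, pairs with Dist < 2 kept."""
    nA, nB = len(A), len(B)
    D = np.full((nA, nB), _UNMATCHABLE_DIST)
    I = np.zeros((nA, nB))
    for ia in range(nA):
        for ib in range(nB):
            v = iou(A.masks[ia], B.masks[ib])
            I[ia, ib] = v
            if v >= 0.5:
                D[ia, ib] = 1.0 - v
    rows, cols = linear_sum_assignment(D)
    pairs, ious = [], []
    for r, c in zip(rows, cols):
        if D[r, c] < _UNMATCHABLE_DIST:
            pairs.append((int(A.ids[r]), int(B.ids[c])))
            ious.append(float(I[r, c]))
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    return MaskMatch(
        pairs=pairs,
        unmatched_a=[int(i) for i in A.ids if int(i) not in matched_a],
        unmatched_b=[int(i) for i in B.ids if int(i) not in matched_b],
        ious=ious,
    )


@dataclass
class FoldResult:
    """One leave-one-out fold: the held-out video, the parameters chosen
    on the training videos, and the held-out F1."""

    test_video: int
    th_snr: float
    alpha: float
    test_f1: float


def grid_search_cv(
    f1_scores: np.ndarray,
    th_grid: list[float],
    alpha_grid: list[float],
) -> tuple[list[FoldResult], float]:
    """Leave-one-out cross-validation over a (video, th, α) F1 tensor.

    ``f1_scores[v, i, j]`` is the F1 of video ``v`` at ``th_grid[i]``,
    ``alpha_grid[j]``.  Each fold holds out one video, picks the (th, α)
    maximizing the mean training F1 (ties: smaller α, then smaller th),
    and records the held-out F1 at those parameters.  Returns the folds
    and their mean test F1 — the dataset-level accuracy metric.
    """
    f1_scores = np.asarray(f1_scores, dtype=np.float64)
    n_videos = f1_scores.shape[0]
    if n_videos < 2:
        raise ValueError("cross-validation needs at least 2 videos")
    if len(th_grid) == 0 or len(alpha_grid) == 0:
        raise ValueError("empty parameter grid")
    if f1_scores.shape != (n_videos, len(th_grid), len(alpha_grid)):
        raise ValueError("score tensor shape does not match the grids")
    # candidate order implements the tie-break: smaller alpha, then smaller th
    candidates = [
        (j, i)
        for j in np.argsort(alpha_grid, kind="stable")
        for i in np.argsort(th_grid, kind="stable")
    ]
    folds = []
    for v in range(n_videos):
        train = np.delete(f1_scores, v, axis=0).mean(axis=0)
        best_score = max(train[i, j] for j, i in candidates)
        j, i = next((j, i) for j, i in candidates if train[i, j] == best_score)
        folds.append(
            FoldResult(
                test_video=v,
                th_snr=float(th_grid[i]),
                alpha=float(alpha_grid[j]),
                test_f1=float(f1_scores[v, i, j]),
            )
        )
    return folds, float(np.mean([f.test_f1 for f in folds]))
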