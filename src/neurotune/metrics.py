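"""Segmentation scoring and the accuracy/time fitness aggregation.

Detections and ground truth are label images (integer per pixel, 0 =
background).  Matching is a one-to-one greedy assignment by descending
pixel overlap: a ground-truth neuron keeps only its best-overlapping
detection, and a detection that overlaps several neurons is credited to the
best one only.  The Overall Dice Coefficient (ODC) scores a whole dataset:

    ODC = 2 * sum(matched overlaps) / (|matched detection px| + |all GT px|)

Per-detection Dice values lambda(delta) against a threshold ``T_dice``
(default 0.5) split detections into true/false positives, from which
precision, recall and F1 follow.

The fitness the optimizers maximize is the weighted harmonic mean

    H = 1 / (a1 / D + a2 / TimeScale),       a1 + a2 = 1,

of detection accuracy D (the ODC) and the speed score
TimeScale = 1 - W / W_max, where W is the candidate's measured wall time
and W_max the largest wall time observed so far across all candidates.
The complementary loss 1 - H is available for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchPair",
    "MatchResult",
    "dice",
    "match_detections",
    "overall_dice",
    "classify_detections",
    "f1_score",
    "precision_recall_f1",
    "time_scale",
    "aggregate_fitness",
    "fitness_loss",
    "frame_rate",
    "score_masks",
]


@dataclass(frozen=True)
class MatchPair:
    detection: int
    truth: int
    overlap: int
    dice: float


@dataclass
class MatchResult:
    pairs: list[MatchPair] = field(default_factory=list)
    unmatched_detections: list[int] = field(default_factory=list)
    unmatched_truth: list[int] = field(default_factory=list)


def dice(region_a: np.ndarray, region_b: np.ndarray) -> float:
    """Dice coefficient of two boolean pixel masks: 2|A&B| / (|A|+|B|).

    Defined as 0 when both regions are empty.
    """
    a = np.asarray(region_a, dtype=bool)
    b = np.asarray(region_b, dtype=bool)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _overlap_table(detections: np.ndarray, truth: np.ndarray):
    """Pixel-overlap counts between every detection and truth label."""
    det = np.asarray(detections)
    gt = np.asarray(truth)
    if det.shape != gt.shape:
        raise ValueError(
            f"mask grids differ: {det.shape} vs {gt.shape}"
        )
    det_ids, det_sizes = np.unique(det[det > 0], return_counts=True)
    gt_ids, gt_sizes = np.unique(gt[gt > 0], return_counts=True)
    both = (det > 0) & (gt > 0)
    overlaps: dict[tuple[int, int], int] = {}
    if both.any():
        pairs, counts = np.unique(
            np.stack([det[both], gt[both]]), axis=1, return_counts=True
        )
        for (d, g), c in zip(pairs.T, counts):
            overlaps[(int(d), int(g))] = int(c)
    return (
        dict(zip(det_ids.tolist(), det_sizes.tolist())),
        dict(zip(gt_ids.tolist(), gt_sizes.tolist())),
        overlaps,
    )


def match_detections(detections: np.ndarray, truth: np.ndarray) -> MatchResult:
    """Greedy one-to-one matching by descending overlap.

    Candidate (detection, truth) pairs with positive overlap are visited in
    order of decreasing overlap (ties broken by label ids for determinism);
    a pair is kept only if neither side is already matched.
    """
    det_sizes, gt_sizes, overlaps = _overlap_table(detections, truth)
    order = sorted(overlaps.items(), key=lambda kv: (-kv[1], kv[0]))
    used_det: set[int] = set()
    used_gt: set[int] = set()
    result = MatchResult()
    for (d, g), ov in order:
        if d in used_det or g in used_gt:
            continue
        used_det.add(d)
        used_gt.add(g)
        lam = 2.0 * ov / (det_sizes[d] + gt_sizes[g])
        result.pairs.append(MatchPair(d, g, ov, lam))
    result.unmatched_detections = sorted(set(det_sizes) - used_det)
    result.unmatched_truth = sorted(set(gt_sizes) - used_gt)
    return result


def overall_dice(detections: np.ndarray, truth: np.ndarray) -> float:
    """Dataset-level Dice between matched detections and the full truth
    mask.  Unmatched detections do not enter the denominator (they are
    penalized through precision instead); unmatched truth pixels do.
    Empty ground truth scores 0.
    """
    det_sizes, gt_sizes, _ = _overlap_table(detections, truth)
    if not gt_sizes:
        return 0.0
    match = match_detections(detections, truth)
    total_overlap = sum(p.overlap for p in match.pairs)
    matched_det_px = sum(det_sizes[p.detection] for p in match.pairs)
    gt_px = sum(gt_sizes.values())
    denom = matched_det_px + gt_px
    return 2.0 * total_overlap / denom if denom else 0.0


def classify_detections(match: MatchResult, t_dice: float = 0.5) -> tuple[int, int]:
    """Split detections into (TP, FP) counts: a matched detection with
    lambda(delta) >= t_dice is a true positive; every other detection
    (below threshold or unmatched) is a false positive."""
    if not 0.0 <= t_dice <= 1.0:
        raise ValueError("t_dice must be in [0, 1]")
    tp = sum(1 for p in match.pairs if p.dice >= t_dice)
    fp = len(match.pairs) - tp + len(match.unmatched_detections)
    return tp, fp


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(tp: int, fp: int, n_truth: int) -> tuple[float, float, float]:
    """Precision TP/(TP+FP), recall TP/|GT|, and their harmonic mean F1;
    zero denominators give 0."""
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / n_truth if n_truth > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


def time_scale(w: float, w_max: float) -> tuple[float, float]:
    """Normalized execution time tau = W/W_max and the maximized speed
    score TimeScale = 1 - tau.  Requires 0 < W <= W_max (callers update the
    running maximum first)."""
    if not 0 < w <= w_max:
        raise ValueError(f"need 0 < W <= W_max, got W={w}, W_max={w_max}")
    tau = w / w_max
    return tau, 1.0 - tau


def aggregate_fitness(d: float, timescale: float, a1: float = 0.8,
                      a2: float | None = None) -> float:
    """Weighted harmonic mean H = 1/(a1/D + a2/TimeScale), the quantity
    the optimizers maximize; H = 0 when either component is 0."""
    if a2 is None:
        a2 = 1.0 - a1
    if not (a1 > 0 and a2 > 0) or abs(a1 + a2 - 1.0) > 1e-12:
        raise ValueError("weights must be positive and sum to 1")
    if not (0.0 <= d <= 1.0 and 0.0 <= timescale <= 1.0):
        raise ValueError("D and TimeScale must be in [0, 1]")
    if d == 0.0 or timescale == 0.0:
        return 0.0
    return 1.0 / (a1 / d + a2 / timescale)


def fitness_loss(d: float, timescale: float, a1: float = 0.8,
                 a2: float | None = None) -> float:
    """The printed loss form 1 - H of the aggregated fitness."""
    return 1.0 - aggregate_fitness(d, timescale, a1, a2)


def frame_rate(n_frames: int, t_total: float) -> float:
    """Throughput rho = n_f / t_tot in frames per second."""
    if t_total <= 0:
        raise ValueError("total time must be positive")
    return n_frames / t_total


def score_masks(detections: np.ndarray, truth: np.ndarray,
                t_dice: float = 0.5) -> dict[str, float]:
    """Full segmentation report for one detection result."""
    match = match_detections(detections, truth)
    tp, fp = classify_detections(match, t_dice)
    n_truth = len(match.pairs) + len(match.unmatched_truth)
    precision, recall, f1 = precision_recall_f1(tp, fp, n_truth)
    return {
        "odc": overall_dice(detections, truth),
        "tp": float(tp),
        "fp": float(fp),
        "n_truth": float(n_truth),
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
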