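"""Segmentation scoring and fitness aggregation."""

import numpy as np
import pytest
from skimage import measure

import neurotune as nt
from neurotune.metrics import MatchResult, MatchPair


def _mask(shape, coords_by_label):
    out = np.zeros(shape, dtype=int)
    for label, coords in coords_by_label.items():
        for y, x in coords:
            out[y, x] = label
    return out


def _box(y0, y1, x0, x1):
    return [(y, x) for y in range(y0, y1) for x in range(x0, x1)]


# -- dice -------------------------------------------------------------------

def test_dice_identical_disjoint_half():
    a = np.zeros((4, 4), bool)
    a[:2, :2] = True
    assert nt.dice(a, a) == 1.0
    b = np.zeros((4, 4), bool)
    b[2:, 2:] = True
    assert nt.dice(a, b) == 0.0
    c = np.zeros((4, 4), bool)
    c[:2, 1:3] = True  # |A|=4, |B|=4, overlap 2
    assert nt.dice(a, c) == pytest.approx(0.5)


def test_dice_both_empty_defined_zero():
    z = np.zeros((3, 3), bool)
    assert nt.dice(z, z) == 0.0


def test_dice_symmetric_random(rng):
    for _ in range(20):
        a = rng.random((8, 8)) < 0.4
        b = rng.random((8, 8)) < 0.4
        assert nt.dice(a, b) == nt.dice(b, a)
        assert 0.0 <= nt.dice(a, b) <= 1.0


# -- matching ---------------------------------------------------------------

def test_one_detection_over_two_truth_keeps_best():
    gt = _mask((8, 12), {1: _box(0, 2, 0, 5), 2: _box(4, 5, 0, 3)})
    det = _mask((8, 12), {1: _box(0, 2, 0, 5) + _box(4, 5, 0, 3)})
    det[4, 0] = det[4, 1] = det[4, 2] = 1
    m = nt.match_detections(det, gt)
    assert len(m.pairs) == 1
    assert m.pairs[0].truth == 1  # the 10-px overlap wins over the 3-px
    assert m.unmatched_truth == [2]


def test_two_detections_over_one_truth_keeps_best():
    gt = _mask((6, 10), {1: _box(0, 2, 0, 5)})  # 10 px
    det = _mask((6, 10), {1: _box(0, 2, 0, 4), 2: _box(1, 2, 4, 9)})
    # det 1 overlaps 8 px, det 2 overlaps 1 px
    m = nt.match_detections(det, gt)
    assert len(m.pairs) == 1
    assert m.pairs[0].detection == 1
    assert m.unmatched_detections == [2]


def test_identical_masks_match_perfectly():
    gt = _mask((10, 10), {1: _box(0, 2, 0, 2), 2: _box(4, 6, 4, 6),
                          3: _box(7, 9, 0, 2)})
    m = nt.match_detections(gt, gt)
    assert len(m.pairs) == 3
    assert all(p.dice == 1.0 for p in m.pairs)
    assert not m.unmatched_detections and not m.unmatched_truth


def test_grid_mismatch_rejected():
    with pytest.raises(ValueError):
        nt.match_detections(np.zeros((4, 4), int), np.zeros((5, 5), int))


# -- overall dice -----------------------------------------------------------

def test_overall_dice_limits():
    gt = _mask((8, 8), {1: _box(0, 3, 0, 3)})
    assert nt.overall_dice(gt, gt) == 1.0
    assert nt.overall_dice(np.zeros_like(gt), gt) == 0.0
    assert nt.overall_dice(gt, np.zeros_like(gt)) == 0.0  # empty truth


def test_overall_dice_toy_example():
    """Two 10-px neurons, one 10-px detection overlapping 8 px of one:
    ODC = 2*8 / (10 + 20)."""
    gt = _mask((10, 12), {1: _box(0, 2, 0, 5), 2: _box(5, 7, 0, 5)})
    det = _mask((10, 12), {1: _box(0, 2, 1, 5) + _box(3, 4, 0, 2)})
    m = nt.match_detections(det, gt)
    assert m.pairs[0].overlap == 8
    assert nt.overall_dice(det, gt) == pytest.approx(16 / 30)


# -- brute-force oracle ------------------------------------------------------

def brute_force_match(det, gt):
    """Independent greedy matcher: explicit double loop over label pairs."""
    pairs = []
    for d in np.unique(det[det > 0]):
        for g in np.unique(gt[gt > 0]):
            ov = int(np.sum((det == d) & (gt == g)))
            if ov > 0:
                pairs.append((ov, int(d), int(g)))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_d, used_g, kept = set(), set(), []
    for ov, d, g in pairs:
        if d in used_d or g in used_g:
            continue
        used_d.add(d)
        used_g.add(g)
        kept.append((d, g, ov))
    return kept


def brute_force_odc(det, gt):
    kept = brute_force_match(det, gt)
    if not np.any(gt > 0):
        return 0.0
    overlap = sum(ov for _, _, ov in kept)
    det_px = sum(int(np.sum(det == d)) for d, _, _ in kept)
    gt_px = int(np.sum(gt > 0))
    return 2.0 * overlap / (det_px + gt_px) if det_px + gt_px else 0.0


def random_label_mask(rng, max_side=32):
    h = int(rng.integers(4, max_side + 1))
    w = int(rng.integers(4, max_side + 1))
    return measure.label(rng.random((h, w)) < rng.uniform(0.05, 0.4)), (h, w)


def test_matching_and_odc_agree_with_oracle(rng):
    for _ in range(60):
        det, shape = random_label_mask(rng)
        gt = measure.label(rng.random(shape) < rng.uniform(0.05, 0.4))
        mine = nt.match_detections(det, gt)
        oracle = brute_force_match(det, gt)
        assert [(p.detection, p.truth, p.overlap) for p in mine.pairs] == oracle
        assert nt.overall_dice(det, gt) == pytest.approx(
            brute_force_odc(det, gt)
        )


# -- classification / precision / recall ------------------------------------

def test_threshold_is_inclusive():
    m = MatchResult(pairs=[MatchPair(1, 1, 5, 0.5)])
    assert nt.classify_detections(m, 0.5) == (1, 0)


def test_unmatched_detection_is_false_positive():
    m = MatchResult(pairs=[], unmatched_detections=[1])
    assert nt.classify_detections(m, 0.5) == (0, 1)


def test_mixed_dice_values_split():
    m = MatchResult(pairs=[MatchPair(1, 1, 5, 0.9), MatchPair(2, 2, 2, 0.4)])
    assert nt.classify_detections(m, 0.5) == (1, 1)


def test_precision_recall_f1_zero_cases():
    assert nt.precision_recall_f1(0, 0, 5) == (0.0, 0.0, 0.0)
    assert nt.precision_recall_f1(0, 3, 0) == (0.0, 0.0, 0.0)


def test_f1_is_harmonic_mean_of_precision_recall(rng):
    for _ in range(20):
        tp = int(rng.integers(0, 20))
        fp = int(rng.integers(0, 20))
        n_gt = int(rng.integers(1, 30))
        p, r, f1 = nt.precision_recall_f1(tp, fp, n_gt)
        assert f1 == pytest.approx(nt.f1_score(p, r))


# -- time scaling and fitness aggregation ------------------------------------

@pytest.mark.parametrize("w, wmax, tau, ts", [
    (8.0, 8.0, 1.0, 0.0),
    (4.0, 8.0, 0.5, 0.5),
    (2.0, 8.0, 0.25, 0.75),
])
def test_time_scale_values(w, wmax, tau, ts):
    got_tau, got_ts = nt.time_scale(w, wmax)
    assert got_tau == pytest.approx(tau)
    assert got_ts == pytest.approx(ts)


def test_time_scale_contract_violation():
    with pytest.raises(ValueError):
        nt.time_scale(9.0, 8.0)  # W exceeds the running maximum
    with pytest.raises(ValueError):
        nt.time_scale(0.0, 8.0)


def test_aggregate_fitness_closed_forms():
    assert nt.aggregate_fitness(1.0, 1.0) == pytest.approx(1.0)
    assert nt.aggregate_fitness(0.5, 0.5, a1=0.5) == pytest.approx(0.5)
    assert nt.aggregate_fitness(0.8, 0.4, a1=0.8) == pytest.approx(2 / 3)
    assert nt.aggregate_fitness(0.0, 0.9) == 0.0
    assert nt.aggregate_fitness(0.9, 0.0) == 0.0


def test_aggregate_fitness_loss_complement():
    from neurotune.metrics import fitness_loss

    assert fitness_loss(0.8, 0.4, a1=0.8) == pytest.approx(1 / 3)


def test_aggregate_fitness_bounds_and_monotonicity():
    grid = np.linspace(0.05, 1.0, 12)
    for d in grid:
        for ts in grid:
            h = nt.aggregate_fitness(d, ts)
            assert min(d, ts) - 1e-12 <= h <= max(d, ts) + 1e-12
            assert h <= 0.8 * d + 0.2 * ts + 1e-12  # below arithmetic mean
    # strictly increasing in each argument
    row = [nt.aggregate_fitness(d, 0.5) for d in grid]
    col = [nt.aggregate_fitness(0.5, ts) for ts in grid]
    assert np.all(np.diff(row) > 0)
    assert np.all(np.diff(col) > 0)


def test_aggregate_fitness_invalid_weights():
    with pytest.raises(ValueError):
        nt.aggregate_fitness(0.5, 0.5, a1=0.0)
    with pytest.raises(ValueError):
        nt.aggregate_fitness(0.5, 0.5, a1=0.7, a2=0.5)


@pytest.mark.parametrize("n, t, rho", [(100, 1.0, 100.0),
                                       (100, 0.5, 200.0),
                                       (0, 2.0, 0.0)])
def test_frame_rate(n, t, rho):
    assert nt.frame_rate(n, t) == pytest.approx(rho)


def test_frame_rate_rejects_nonpositive_time():
    with pytest.raises(ValueError):
        nt.frame_rate(10, 0.0)
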