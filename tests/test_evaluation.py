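import math

import numpy as np
import pytest

from uqseg import (
    PatchCounts,
    find_threshold_for_remaining_ratio,
    patch_counts,
    pooled_segmentation_metrics,
    removal_analysis,
    segmentation_metrics,
    threshold_sweep,
    uncertainty_eval,
)

from _oracles import patch_tallies, pixel_metrics


# ------------------------------------------------------------ pixel metrics
def test_perfect_prediction():
    gt = np.array([[1, 0], [0, 1]])
    rep = segmentation_metrics(gt.copy(), gt)
    assert rep.pixel_accuracy == 1.0
    assert rep.per_class_iou == {0: 1.0, 1: 1.0}
    assert rep.mean_iou == 1.0 and rep.weighted_iou == 1.0 and rep.dice == 1.0


def test_worked_two_by_two_example():
    pred = np.array([[1, 1], [0, 0]])
    gt = np.array([[1, 0], [0, 0]])
    rep = segmentation_metrics(pred, gt)
    assert rep.per_class_iou[1] == pytest.approx(1 / 2)
    assert rep.per_class_iou[0] == pytest.approx(2 / 3)
    assert rep.mean_iou == pytest.approx(7 / 12)
    assert rep.pixel_accuracy == pytest.approx(3 / 4)
    assert rep.dice == pytest.approx(2 / 3)
    # weighted IoU: w0 = 3/4, w1 = 1/4
    assert rep.weighted_iou == pytest.approx(0.75 * 2 / 3 + 0.25 * 0.5)


def test_metrics_match_pixel_oracle(rng):
    for trial in range(200):
        pred = rng.integers(0, 2, size=(8, 8))
        gt = rng.integers(0, 2, size=(8, 8))
        valid = rng.random((8, 8)) > 0.3 if trial % 2 else None
        if valid is not None and not valid.any():
            continue
        rep = segmentation_metrics(pred, gt, valid_mask=valid)
        exp = pixel_metrics(pred.tolist(), gt.tolist(), None if valid is None else valid.tolist())
        assert rep.pixel_accuracy == exp["pixel_accuracy"]
        assert rep.mean_iou == pytest.approx(exp["mean_iou"], abs=1e-12)
        assert rep.weighted_iou == pytest.approx(exp["weighted_iou"], abs=1e-12)
        assert rep.dice == pytest.approx(exp["dice"], abs=1e-12) or (
            math.isnan(rep.dice) and math.isnan(exp["dice"])
        )
        for c in (0, 1):
            a, b = rep.per_class_iou[c], exp["per_class_iou"][c]
            assert a == pytest.approx(b, abs=1e-12) or (math.isnan(a) and math.isnan(b))


def test_metrics_validation():
    with pytest.raises(ValueError, match="shape"):
        segmentation_metrics(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(ValueError, match="valid"):
        segmentation_metrics(
            np.zeros((2, 2)), np.zeros((2, 2)), valid_mask=np.zeros((2, 2), dtype=bool)
        )


def test_pooled_metrics_pool_pixel_counts(rng):
    preds = [rng.integers(0, 2, size=(4, 4)) for _ in range(3)]
    gts = [rng.integers(0, 2, size=(4, 4)) for _ in range(3)]
    pooled = pooled_segmentation_metrics(list(zip(preds, gts)))
    big_pred = np.concatenate([p.ravel() for p in preds])[None, :]
    big_gt = np.concatenate([g.ravel() for g in gts])[None, :]
    single = segmentation_metrics(big_pred, big_gt)
    assert pooled.pixel_accuracy == single.pixel_accuracy
    assert pooled.mean_iou == pytest.approx(single.mean_iou)


# ------------------------------------------------------------ patch metrics
def test_all_accurate_certain():
    gt = np.zeros((4, 4), dtype=int)
    counts = patch_counts(gt, gt, np.zeros((4, 4)), uncertainty_threshold=0.5)
    assert (counts.nac, counts.nau, counts.nic, counts.niu) == (4, 0, 0, 0)


def test_half_correct_patch_is_inaccurate():
    pred = np.array([[1, 1], [0, 0]])
    gt = np.array([[1, 0], [1, 0]])  # exactly 2 of 4 correct
    counts = patch_counts(pred, gt, np.zeros((2, 2)), uncertainty_threshold=0.5)
    assert counts.nic == 1 and counts.nac == 0  # 0.5 is NOT > 0.5


def test_patch_counts_match_enumeration_oracle(rng):
    thresholds = np.linspace(0.0, 1.0, 11)
    for _ in range(30):
        pred = rng.integers(0, 2, size=(8, 8))
        gt = rng.integers(0, 2, size=(8, 8))
        unc = rng.random((8, 8))
        for t in thresholds:
            c = patch_counts(pred, gt, unc, uncertainty_threshold=float(t))
            assert (c.nac, c.nau, c.nic, c.niu) == patch_tallies(
                pred.tolist(), gt.tolist(), unc.tolist(), float(t)
            )


def test_patch_conservation(rng):
    pred = rng.integers(0, 2, size=(10, 10))
    gt = rng.integers(0, 2, size=(10, 10))
    unc = rng.random((10, 10))
    counts = patch_counts(pred, gt, unc, uncertainty_threshold=0.4)
    assert counts.total == (10 // 2) * (10 // 2)


def test_odd_size_truncates_with_warning(rng):
    pred = rng.integers(0, 2, size=(5, 5))
    with pytest.warns(UserWarning, match="truncating"):
        counts = patch_counts(pred, pred, np.zeros((5, 5)), uncertainty_threshold=0.5)
    assert counts.total == 4


def test_uncertainty_eval_hand_example():
    ev = uncertainty_eval(PatchCounts(nac=6, nau=1, nic=2, niu=3))
    assert ev.p_accurate_given_certain == pytest.approx(0.75)
    assert ev.p_uncertain_given_inaccurate == pytest.approx(0.6)
    assert ev.pavpu == pytest.approx(0.75)


def test_uncertainty_eval_degenerate_denominators():
    ev = uncertainty_eval(PatchCounts(nac=3, nau=1, nic=0, niu=0))
    assert math.isnan(ev.p_uncertain_given_inaccurate)
    assert ev.pavpu == pytest.approx(3 / 4)
    ev2 = uncertainty_eval(PatchCounts(nac=0, nau=2, nic=0, niu=0))
    assert math.isnan(ev2.p_accurate_given_certain)


def test_all_accurate_certain_metrics_are_one():
    ev = uncertainty_eval(PatchCounts(nac=9, nau=0, nic=0, niu=0))
    assert ev.p_accurate_given_certain == 1.0
    assert ev.pavpu == 1.0


# ------------------------------------------------------------------- sweeps
def test_sweep_limits(rng):
    pred = rng.integers(0, 2, size=(8, 8))
    gt = rng.integers(0, 2, size=(8, 8))
    unc = rng.uniform(0.2, 0.8, size=(8, 8))
    evals = threshold_sweep(pred, gt, unc, np.array([0.0, 1.0]))
    counts_hi = patch_counts(pred, gt, unc, uncertainty_threshold=1.0)
    accurate_fraction = (counts_hi.nac + counts_hi.nau) / counts_hi.total
    # threshold >= max uncertainty: everything certain
    assert evals[1].p_accurate_given_certain == pytest.approx(accurate_fraction)
    assert counts_hi.nau == 0 and counts_hi.niu == 0
    # threshold below min uncertainty: everything uncertain
    counts_lo = patch_counts(pred, gt, unc, uncertainty_threshold=0.0)
    assert counts_lo.nac == 0 and counts_lo.nic == 0
    inaccurate_fraction = counts_lo.niu / counts_lo.total
    assert evals[0].pavpu == pytest.approx(inaccurate_fraction)


def test_sweep_consistent_with_direct_call(rng):
    pred = rng.integers(0, 2, size=(6, 6))
    gt = rng.integers(0, 2, size=(6, 6))
    unc = rng.random((6, 6))
    [ev] = threshold_sweep(pred, gt, unc, np.array([0.3]))
    direct = uncertainty_eval(
        patch_counts(pred, gt, unc, uncertainty_threshold=0.3), uncertainty_threshold=0.3
    )
    assert ev == direct


def test_sweep_writes_csv(tmp_path, rng):
    pred = rng.integers(0, 2, size=(4, 4))
    out = tmp_path / "sweep.csv"
    threshold_sweep(pred, pred, rng.random((4, 4)), np.linspace(0, 1, 5), csv_path=out)
    import pandas as pd

    frame = pd.read_csv(out)
    assert list(frame.columns) == [
        "threshold", "p_accurate_given_certain", "p_uncertain_given_inaccurate", "pavpu",
    ]
    assert len(frame) == 5


def test_sweep_empty_grid_raises(rng):
    pred = rng.integers(0, 2, size=(4, 4))
    with pytest.raises(ValueError, match="empty"):
        threshold_sweep(pred, pred, np.zeros((4, 4)), np.array([]))


# ---------------------------------------------------------- removal analysis
def test_removal_identity_at_threshold_one(rng):
    pred = rng.integers(0, 2, size=(8, 8))
    gt = rng.integers(0, 2, size=(8, 8))
    unc = rng.random((8, 8))
    curve = removal_analysis(pred, gt, unc, np.array([0.5, 1.0]))
    assert curve.remaining_pixel_ratio[1] == 1.0
    unmasked = segmentation_metrics(pred, gt)
    assert curve.reports[1].pixel_accuracy == unmasked.pixel_accuracy
    assert curve.reports[1].mean_iou == unmasked.mean_iou
    assert curve.reports[1].weighted_iou == unmasked.weighted_iou
    assert (np.diff(curve.remaining_pixel_ratio) >= 0).all()


def test_removal_flat_curve_for_zero_uncertainty(rng):
    pred = rng.integers(0, 2, size=(8, 8))
    gt = rng.integers(0, 2, size=(8, 8))
    curve = removal_analysis(pred, gt, np.zeros((8, 8)), np.linspace(0, 1, 5))
    unmasked = segmentation_metrics(pred, gt)
    for rep, ratio in zip(curve.reports, curve.remaining_pixel_ratio):
        assert ratio == 1.0
        assert rep.pixel_accuracy == unmasked.pixel_accuracy


def test_removal_planted_errors_in_top_decile(rng):
    """All errors carry top-decile uncertainty: removing it gives accuracy 1."""
    gt = rng.integers(0, 2, size=(10, 10))
    pred = gt.copy()
    err = rng.random((10, 10)) < 0.1
    pred[err] = 1 - gt[err]
    unc = rng.uniform(0.0, 0.5, size=(10, 10))
    unc[err] = rng.uniform(0.95, 1.0, size=int(err.sum()))
    curve = removal_analysis(pred, gt, unc, np.array([0.9, 1.0]))
    assert curve.reports[0].pixel_accuracy == 1.0
    assert curve.reports[1].pixel_accuracy < 1.0


def test_removal_all_pixels_removed_gives_sentinel_point():
    pred = np.zeros((4, 4), dtype=int)
    unc = np.full((4, 4), 0.8)
    curve = removal_analysis(pred, pred, unc, np.array([0.1, 1.0]))
    assert curve.reports[0] is None
    assert curve.remaining_pixel_ratio[0] == 0.0
    assert curve.reports[1] is not None


# ------------------------------------------------------- threshold for ratio
def test_threshold_for_full_ratio_is_one():
    assert find_threshold_for_remaining_ratio(np.random.default_rng(0).random(50), 1.0) == 1.0


def test_threshold_quantile_oracle():
    values = (np.arange(100) + 0.5) / 100.0  # 100 distinct values
    rng = np.random.default_rng(1)
    unc = values[rng.permutation(100)].reshape(10, 10)
    t = find_threshold_for_remaining_ratio(unc, 0.9)
    assert t == np.sort(values)[89]
    remaining = np.mean(unc <= t)
    assert 0.90 <= remaining <= 0.91


def test_threshold_monotone_in_target(rng):
    unc = rng.random(200)
    targets = [0.1, 0.3, 0.5, 0.7, 0.9, 1.0]
    ts = [find_threshold_for_remaining_ratio(unc, t) for t in targets]
    assert all(a <= b for a, b in zip(ts, ts[1:]))


def test_threshold_target_validation(rng):
    with pytest.raises(ValueError):
        find_threshold_for_remaining_ratio(rng.random(10), 0.0)
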