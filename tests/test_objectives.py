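"""Loss and metric arithmetic, including the exact complementarity of the
generator-adversarial and discriminator objectives."""

import numpy as np
import pytest

from scintiseg import nn
from scintiseg.discriminator import CriticConfig, build_critic
from scintiseg.generator import SegOutputs
from scintiseg.objectives import (ConfusionCounts, LossWeights, adv_loss_G,
                                  confusion_counts, dice_coefficient, disc_loss,
                                  evaluate, seg_loss, soft_dice,
                                  summarize_runs, total_gen_loss)

CRITIC = build_critic(CriticConfig(layers=2, base_channels=4, seed=0))
CRITIC.eval()


def _heads(arrays):
    return SegOutputs([nn.Tensor(a.astype(np.float32)) for a in arrays])


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def test_dice_perfect_overlap_is_one(rng):
    gt = (rng.random((16, 16)) > 0.6).astype(float)
    assert dice_coefficient(gt, gt, smooth=0.0) == pytest.approx(1.0)


def test_dice_disjoint_is_zero_as_smooth_vanishes():
    a = np.zeros((8, 8))
    b = np.zeros((8, 8))
    a[:2] = 1
    b[6:] = 1
    assert dice_coefficient(a, b, smooth=0.0) == 0.0
    assert dice_coefficient(a, b, smooth=1e-9) == pytest.approx(0.0, abs=1e-9)


def test_dice_from_confusion_counts():
    """TP=3, FP=1, FN=2 -> Dice 2*3/(2*3+1+2) = 0.6667 = 2PR/(P+R)."""
    pred = np.zeros(10)
    gt = np.zeros(10)
    pred[:4] = 1          # 4 positives predicted
    gt[1:6] = 1           # 5 true positives exist; overlap = indices 1,2,3
    c = confusion_counts(pred, gt)
    assert (c.tp, c.fp, c.fn) == (3, 1, 2)
    assert dice_coefficient(pred, gt, smooth=0.0) == pytest.approx(2 * 3 / 9)
    p, r = 0.75, 0.6
    assert 2 * p * r / (p + r) == pytest.approx(2 * 3 / 9)


def test_soft_dice_equals_count_dice_on_binary_pairs(rng):
    """Oracle equivalence on 200 random binary mask pairs."""
    for _ in range(200):
        pred = (rng.random((12, 12)) > rng.random()).astype(float)
        gt = (rng.random((12, 12)) > rng.random()).astype(float)
        c = confusion_counts(pred, gt)
        denom = 2 * c.tp + c.fp + c.fn
        expected = 2 * c.tp / denom if denom else 1.0
        soft = soft_dice(nn.Tensor(pred), nn.Tensor(gt), smooth=1e-12).item()
        assert soft == pytest.approx(expected, abs=1e-5)


# ---------------------------------------------------------------------------
# segmentation loss
# ---------------------------------------------------------------------------

def test_seg_loss_perfect_heads_is_zero(rng):
    gt = (rng.random((1, 1, 8, 8)) > 0.7).astype(np.float32)
    out = _heads([gt] * 4)
    assert seg_loss(out, nn.Tensor(gt), LossWeights(), smooth=0.0).item() == 0.0


def test_seg_loss_disjoint_heads_is_one():
    gt = np.zeros((1, 1, 8, 8), np.float32)
    gt[..., :2, :] = 1
    pred = np.zeros_like(gt)
    pred[..., 6:, :] = 1
    out = _heads([pred] * 4)
    assert seg_loss(out, nn.Tensor(gt), LossWeights(), smooth=1e-12).item() \
        == pytest.approx(1.0, abs=1e-6)


def test_seg_loss_mixed_heads_averages():
    """Heads with Dice {1,1,0,0} at equal weights -> loss 0.5."""
    gt = np.zeros((1, 1, 8, 8), np.float32)
    gt[..., :4, :] = 1
    far = np.zeros_like(gt)
    far[..., 6:, :] = 1
    out = _heads([gt, gt, far, far])
    val = seg_loss(out, nn.Tensor(gt), LossWeights(), smooth=1e-12).item()
    assert val == pytest.approx(0.5, abs=1e-6)


def test_seg_loss_monotone_under_corruption(rng):
    """Flipping foreground pixels of a perfect prediction never lowers it."""
    gt = (rng.random((1, 1, 8, 8)) > 0.5).astype(np.float32)
    prev = 0.0
    pred = gt.copy()
    fg = np.argwhere(gt[0, 0] > 0)
    w = LossWeights()
    for k in range(len(fg)):
        pred[0, 0, fg[k][0], fg[k][1]] = 0.0
        val = seg_loss(_heads([pred] * 4), nn.Tensor(gt), w).item()
        assert val >= prev - 1e-7
        prev = val


def test_seg_loss_bce_kinds(rng):
    gt = (rng.random((1, 1, 8, 8)) > 0.7).astype(np.float32)
    out = _heads([np.full_like(gt, 0.5)] * 4)
    bce = seg_loss(out, nn.Tensor(gt), LossWeights(seg_loss_kind="bce")).item()
    assert bce == pytest.approx(np.log(2), rel=1e-4)  # 0.5 everywhere
    both = seg_loss(out, nn.Tensor(gt),
                    LossWeights(seg_loss_kind="dice_plus_bce")).item()
    dice_only = seg_loss(out, nn.Tensor(gt), LossWeights()).item()
    assert both == pytest.approx(dice_only + bce, rel=1e-4)


# ---------------------------------------------------------------------------
# adversarial losses
# ---------------------------------------------------------------------------

def test_adv_loss_zero_when_heads_equal_gt(rng):
    gt = (rng.random((1, 1, 16, 16)) > 0.7).astype(np.float32)
    img = rng.random((1, 1, 16, 16)).astype(np.float32)
    out = _heads([gt] * 4)
    assert adv_loss_G(out, nn.Tensor(gt), nn.Tensor(img), CRITIC).item() == 0.0
    assert disc_loss(out, nn.Tensor(gt), nn.Tensor(img), CRITIC).item() == 1.0


def test_adv_plus_disc_is_one_on_1000_random_pairs(rng):
    """Exact complementarity of the two adversarial objectives."""
    worst = 0.0
    for _ in range(1000):
        gt = (rng.random((1, 1, 16, 16)) > rng.random()).astype(np.float32)
        img = rng.random((1, 1, 16, 16)).astype(np.float32)
        out = _heads([rng.random((1, 1, 16, 16))])
        a = adv_loss_G(out, nn.Tensor(gt), nn.Tensor(img), CRITIC).item()
        d = disc_loss(out, nn.Tensor(gt), nn.Tensor(img), CRITIC).item()
        worst = max(worst, abs(a + d - 1.0))
        assert 0.0 <= a <= 1.0  # normalized signatures keep disc_loss >= 0
    assert worst <= 1e-6


def test_adv_loss_symmetric_in_pred_and_gt(rng):
    gt = (rng.random((1, 1, 16, 16)) > 0.6).astype(np.float32)
    pred = rng.random((1, 1, 16, 16)).astype(np.float32)
    img = rng.random((1, 1, 16, 16)).astype(np.float32)
    a = adv_loss_G(_heads([pred]), nn.Tensor(gt), nn.Tensor(img), CRITIC).item()
    b = adv_loss_G(_heads([gt]), nn.Tensor(pred), nn.Tensor(img), CRITIC).item()
    assert a == pytest.approx(b, rel=1e-5)


def test_total_gen_loss_weighting(rng):
    gt = (rng.random((1, 1, 16, 16)) > 0.7).astype(np.float32)
    img = rng.random((1, 1, 16, 16)).astype(np.float32)
    pred = rng.random((1, 1, 16, 16)).astype(np.float32)
    out = _heads([pred] * 4)
    seg_only = total_gen_loss(out, nn.Tensor(gt), nn.Tensor(img), CRITIC,
                              LossWeights(alpha=1, beta=0)).item()
    assert seg_only == pytest.approx(
        seg_loss(out, nn.Tensor(gt), LossWeights()).item(), rel=1e-6)
    adv_only = total_gen_loss(out, nn.Tensor(gt), nn.Tensor(img), CRITIC,
                              LossWeights(alpha=0, beta=1)).item()
    assert adv_only == pytest.approx(
        adv_loss_G(out, nn.Tensor(gt), nn.Tensor(img), CRITIC).item(), rel=1e-6)
    perfect = _heads([gt] * 4)
    assert total_gen_loss(perfect, nn.Tensor(gt), nn.Tensor(img), CRITIC,
                          LossWeights(), ).item() <= 1e-6


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def test_evaluate_perfect_predictions(rng):
    masks = [(rng.random((8, 8)) > 0.5).astype(np.uint8) for _ in range(3)]
    report = evaluate(masks, masks)
    assert (report.dsc, report.precision, report.recall) == (1.0, 1.0, 1.0)


def test_evaluate_single_image_counts():
    pred = np.zeros(10, np.uint8)
    gt = np.zeros(10, np.uint8)
    pred[:4] = 1
    gt[1:6] = 1  # TP=3 FP=1 FN=2
    report = evaluate([pred], [gt])
    assert report.precision == pytest.approx(0.75)
    assert report.recall == pytest.approx(0.6)
    assert report.dsc == pytest.approx(2 * 0.75 * 0.6 / 1.35)


def test_evaluate_empty_prediction_has_zero_recall():
    gt = np.zeros((8, 8), np.uint8)
    gt[2, 2] = 1
    report = evaluate([np.zeros_like(gt)], [gt])
    assert report.recall == 0.0


def test_evaluate_empty_empty_scores_configured_value():
    empty = np.zeros((8, 8), np.uint8)
    assert evaluate([empty], [empty]).dsc == 1.0
    assert evaluate([empty], [empty], empty_value=0.0).dsc == 0.0


def test_evaluate_invariant_to_image_order(rng):
    preds = [(rng.random((8, 8)) > 0.5).astype(np.uint8) for _ in range(5)]
    gts = [(rng.random((8, 8)) > 0.5).astype(np.uint8) for _ in range(5)]
    fwd = evaluate(preds, gts)
    rev = evaluate(preds[::-1], gts[::-1])
    for key, val in fwd.as_dict().items():
        assert rev.as_dict()[key] == pytest.approx(val, rel=1e-12)


def test_summarize_runs_mean_std():
    reports = [evaluate([np.ones((4, 4), np.uint8)], [np.ones((4, 4), np.uint8)])
               for _ in range(3)]
    summary = summarize_runs(reports)
    assert summary["dsc"]["mean"] == 1.0
    assert summary["dsc"]["std"] == 0.0
    assert len(summary["recall"]["runs"]) == 3


def test_confusion_counts_partition_pixels(rng):
    pred = rng.random((9, 9)) > 0.4
    gt = rng.random((9, 9)) > 0.6
    c = confusion_counts(pred, gt)
    assert c.total == 81
    assert isinstance(c, ConfusionCounts)
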