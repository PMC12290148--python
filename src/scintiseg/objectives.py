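"""Losses and evaluation metrics.

Training objective (alternating minimization):

* generator:      L(G) = alpha * L_seg(G) + beta * L_adv(G)
* segmentation:   L_seg(G) = weighted mean over heads of (1 - Dice(y_i, gt));
                  with four equally weighted heads this is
                  (1/4) * sum_i (1 - Dice(y_i, gt))
* adversarial:    L_adv(G) = mean over heads of the multi-scale L1 distance
                  between the critic signatures of y_i*image and gt*image
* discriminator:  L(D) = 1 - L_adv computed on detached generator outputs,
                  so the critic maximizes the signature separation while the
                  generator minimizes it.

Evaluation uses the Dice similarity coefficient, precision and recall from
per-image confusion counts: precision = TP/(TP+FP), recall = TP/(TP+FN),
DSC = 2PR/(P+R) = 2TP/(2TP+FP+FN). Images are scored individually and
averaged over the test set (macro averaging); repeated training runs are
summarized as mean +/- standard deviation per metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .discriminator import Critic, critic_input, critic_signature, multiscale_l1
from .errors import ConfigurationError

__all__ = [
    "LossWeights", "ConfusionCounts", "MetricsReport",
    "dice_coefficient", "soft_dice", "seg_loss", "adv_loss_G", "disc_loss",
    "total_gen_loss", "confusion_counts", "evaluate", "summarize_runs",
]

SEG_LOSS_KINDS = ("dice", "bce", "dice_plus_bce")
_BCE_EPS = 1e-7


@dataclass
class LossWeights:
    alpha: float = 1.0
    beta: float = 1.0
    head_weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    seg_loss_kind: str = "dice"

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or (self.alpha == 0 and self.beta == 0):
            raise ConfigurationError("alpha, beta must be >= 0 and not both zero")
        hw = np.asarray(self.head_weights, dtype=float)
        if (hw < 0).any() or not hw.any():
            raise ConfigurationError("head_weights must be >= 0 and not all zero")
        if self.seg_loss_kind not in SEG_LOSS_KINDS:
            raise ConfigurationError(f"unknown seg_loss_kind {self.seg_loss_kind!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def soft_dice(pred: nn.Tensor, gt: nn.Tensor, smooth: float = 1.0) -> nn.Tensor:
    """Differentiable soft Dice (2*sum(p*g)+s) / (sum(p)+sum(g)+s)."""
    if pred.shape != gt.shape:
        raise ValueError(f"pred shape {pred.shape} != gt shape {gt.shape}")
    inter = nn.sum_(nn.mul(pred, gt))
    denom = nn.add(nn.add(nn.sum_(pred), nn.sum_(gt)), np.float32(smooth))
    return nn.div(nn.add(nn.mul(inter, np.float32(2.0)), np.float32(smooth)), denom)


def dice_coefficient(pred, gt, smooth: float = 1.0) -> float:
    """Soft Dice on arrays in [0,1]; on binarized inputs this equals
    2TP/(2TP+FP+FN), the harmonic combination of precision and recall."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"pred shape {pred.shape} != gt shape {gt.shape}")
    inter = float((pred * gt).sum())
    return (2.0 * inter + smooth) / (pred.sum() + gt.sum() + smooth)


# ---------------------------------------------------------------------------
# training losses (operate on SegOutputs-style head lists of Tensors)
# ---------------------------------------------------------------------------

def _check_binary(gt: nn.Tensor) -> None:
    vals = np.unique(gt.data)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("ground truth must be binary {0,1}")


def _bce(pred: nn.Tensor, gt: nn.Tensor) -> nn.Tensor:
    p = nn.clamp(pred, _BCE_EPS, 1.0 - _BCE_EPS)
    pos = nn.mul(gt, nn.log(p))
    neg_ = nn.mul(nn.sub(np.float32(1.0), gt), nn.log(nn.sub(np.float32(1.0), p)))
    return nn.neg(nn.mean(nn.add(pos, neg_)))


def seg_loss(outputs, gt: nn.Tensor, w: LossWeights, smooth: float = 1.0) -> nn.Tensor:
    """Head-weight-normalized mean of per-head (1 - Dice) (and/or BCE)."""
    heads = outputs.heads if hasattr(outputs, "heads") else list(outputs)
    _check_binary(gt)
    hw = list(w.head_weights)
    if len(heads) == 1:  # deep supervision off: single head, single weight
        hw = [1.0]
    if len(hw) != len(heads):
        raise ValueError(f"{len(heads)} heads but {len(hw)} head weights")
    total = None
    for head, weight in zip(heads, hw):
        if weight == 0:
            continue
        terms = []
        if w.seg_loss_kind in ("dice", "dice_plus_bce"):
            terms.append(nn.sub(np.float32(1.0), soft_dice(head, gt, smooth)))
        if w.seg_loss_kind in ("bce", "dice_plus_bce"):
            terms.append(_bce(head, gt))
        term = terms[0] if len(terms) == 1 else nn.add(terms[0], terms[1])
        term = nn.mul(term, np.float32(weight))
        total = term if total is None else nn.add(total, term)
    return nn.div(total, np.float32(sum(hw)))


def adv_loss_G(outputs, gt: nn.Tensor, image: nn.Tensor, critic: Critic) -> nn.Tensor:
    """Mean over heads of the signature distance between predicted-mask and
    ground-truth-mask critic inputs."""
    heads = outputs.heads if hasattr(outputs, "heads") else list(outputs)
    mode = critic.cfg.input_mode
    sig_gt = critic_signature(critic, critic_input(image, gt, mode))
    total = None
    for head in heads:
        sig = critic_signature(critic, critic_input(image, head, mode))
        d = multiscale_l1(sig, sig_gt)
        total = d if total is None else nn.add(total, d)
    return nn.div(total, np.float32(len(heads)))


def disc_loss(outputs, gt: nn.Tensor, image: nn.Tensor, critic: Critic) -> nn.Tensor:
    """1 - adv_loss_G on critic-detached generator outputs."""
    heads = outputs.heads if hasattr(outputs, "heads") else list(outputs)
    detached = [h.detach() for h in heads]
    return nn.sub(np.float32(1.0), adv_loss_G(detached, gt, image, critic))


def total_gen_loss(outputs, gt: nn.Tensor, image: nn.Tensor, critic: Critic | None,
                   w: LossWeights) -> nn.Tensor:
    """alpha * L_seg + beta * L_adv (the adversarial term needs a critic)."""
    loss = nn.mul(seg_loss(outputs, gt, w), np.float32(w.alpha))
    if w.beta > 0:
        if critic is None:
            raise ConfigurationError("beta > 0 requires a critic")
        loss = nn.add(loss, nn.mul(adv_loss_G(outputs, gt, image, critic),
                                   np.float32(w.beta)))
    return loss


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"pred shape {pred.shape} != gt shape {gt.shape}")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    tn = int((~pred & ~gt).sum())
    return ConfusionCounts(tp, fp, fn, tn)


def _prf(c: ConfusionCounts, empty_value: float) -> tuple[float, float, float]:
    if c.tp + c.fp + c.fn == 0:  # empty gt and empty pred: correct rejection
        return empty_value, empty_value, empty_value
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    dsc = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    return dsc, precision, recall


@dataclass
class MetricsReport:
    dsc: float
    precision: float
    recall: float
    per_image: list[tuple[float, float, float]] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {"dsc": self.dsc, "precision": self.precision, "recall": self.recall}


def evaluate(pred_masks, gt_masks, empty_value: float = 1.0) -> MetricsReport:
    """Macro-averaged DSC/precision/recall over paired mask lists.

    An image whose prediction and ground truth are both empty scores
    ``empty_value`` (default 1: a correct rejection) on all three metrics.
    """
    preds = [getattr(p, "pixels", p) for p in pred_masks]
    gts = [getattr(g, "pixels", g) for g in gt_masks]
    if len(preds) != len(gts):
        raise ValueError(f"{len(preds)} predictions vs {len(gts)} ground truths")
    if not preds:
        raise ValueError("evaluate needs at least one image pair")
    per_image = [_prf(confusion_counts(p, g), empty_value)
                 for p, g in zip(preds, gts)]
    arr = np.asarray(per_image, dtype=np.float64)
    d, p, r = arr.mean(axis=0)
    return MetricsReport(float(d), float(p), float(r), per_image)


def summarize_runs(reports: list[MetricsReport]) -> dict[str, dict[str, float]]:
    """mean +/- std across repeated seeded runs, per metric."""
    out = {}
    for name in ("dsc", "precision", "recall"):
        vals = np.asarray([getattr(r, name) for r in reports], dtype=np.float64)
        out[name] = {"mean": float(vals.mean()),
                     "std": float(vals.std(ddof=0)),
                     "runs": [float(v) for v in vals]}
    return out


def write_report(path: str | Path, summary: dict) -> None:
    import json
    Path(path).write_text(json.dumps(summary, indent=2))
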