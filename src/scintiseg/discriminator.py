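"""Multi-scale critic for adversarial segmentation training.

Instead of emitting a scalar real/fake probability (which yields weak,
unstable gradients for segmentation), the critic maps its input — by default
the elementwise product of the image with a (predicted or ground-truth)
mask — through a cascade of strided convolutions and returns the
concatenation of every stage's flattened feature map as one signature
vector. The adversarial signal is then the L1 distance between the
signatures of the predicted-mask product and the ground-truth product,
which compares the two masks at every spatial scale the critic sees.

Each stage's features are scaled by ``layer_weights[i] / element_count``
before concatenation; the distance divides by the number of stages, so with
unit weights it is the average over scales of the per-scale mean absolute
feature difference. That keeps the distance of typical [0,1]-valued inputs
well below 1, which the discriminator objective (1 minus the distance)
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError

__all__ = ["CriticConfig", "CriticSignature", "Critic", "build_critic",
           "critic_input", "critic_signature", "multiscale_l1"]

INPUT_MODES = ("product", "concat", "sum", "mask_only")


@dataclass
class CriticConfig:
    layers: int = 6
    base_channels: int = 64
    input_mode: str = "product"
    layer_weights: tuple[float, ...] | None = None  # None -> all ones
    seed: int = 42

    def __post_init__(self):
        if self.layers < 2:
            raise ConfigurationError("critic needs at least 2 layers")
        if self.input_mode not in INPUT_MODES:
            raise ConfigurationError(f"unknown input_mode {self.input_mode!r}")
        if self.layer_weights is None:
            self.layer_weights = (1.0,) * self.layers
        w = np.asarray(self.layer_weights, dtype=float)
        if len(w) != self.layers:
            raise ConfigurationError(
                f"layer_weights must have {self.layers} entries, got {len(w)}")
        if (w < 0).any() or not w.any():
            raise ConfigurationError("layer_weights must be >= 0 and not all zero")


@dataclass
class CriticSignature:
    """Weighted multi-layer feature signature, one row per batch sample."""
    vector: nn.Tensor  # shape (N, total_features)
    n_layers: int

    @property
    def length(self) -> int:
        return self.vector.shape[1]


class Critic(nn.Module):
    """Stages of 4x4 stride-2 convs (leaky ReLU 0.2, batch norm except the
    first stage), channel plan base, 2x, 4x, 8x, then capped at 8x."""

    def __init__(self, cfg: CriticConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        in_ch = 2 if cfg.input_mode == "concat" else 1
        self.stages = []
        for i in range(cfg.layers):
            out_ch = cfg.base_channels * min(2 ** i, 8)
            mods = [nn.Conv2d(in_ch, out_ch, 4, stride=2, padding=1, rng=rng)]
            if i > 0:
                mods.append(nn.BatchNorm2d(out_ch))
            mods.append(nn.LeakyReLU(0.2))
            self.stages.append(nn.Sequential(*mods))
            in_ch = out_ch

    def forward(self, x: nn.Tensor) -> list[nn.Tensor]:
        feats = []
        for i, stage in enumerate(self.stages):
            if min(x.shape[2:]) < 2:
                raise ValueError(
                    f"critic input too small: stage {i} sees spatial dims "
                    f"{x.shape[2:]}, needs >= 2 to stride")
            x = stage(x)
            feats.append(x)
        return feats


def build_critic(cfg: CriticConfig) -> Critic:
    return Critic(cfg)


def critic_input(image, mask, mode: str = "product") -> nn.Tensor:
    """Fuse a normalized image with a mask/probability map for the critic.

    ``product`` multiplies them elementwise (the default: the mask carves
    the image, so the critic sees intensity and texture under the mask),
    ``concat`` stacks them as two channels, ``sum`` adds them, and
    ``mask_only`` ignores the image.
    """
    image = image if isinstance(image, nn.Tensor) else nn.Tensor(image)
    mask = mask if isinstance(mask, nn.Tensor) else nn.Tensor(mask)
    if image.shape[2:] != mask.shape[2:]:
        raise ValueError(
            f"image {image.shape[2:]} and mask {mask.shape[2:]} spatial dims differ")
    if mode == "product":
        return nn.mul(image, mask)
    if mode == "concat":
        return nn.concat([image, mask], axis=1)
    if mode == "sum":
        return nn.add(image, mask)
    if mode == "mask_only":
        return mask
    raise ConfigurationError(f"unknown critic input mode {mode!r}")


def critic_signature(model: Critic, x: nn.Tensor) -> CriticSignature:
    """Flatten each stage's features, scale by weight/element-count, concat."""
    n = x.shape[0]
    feats = model(x)
    pieces = []
    for feat, w in zip(feats, model.cfg.layer_weights):
        flat = nn.reshape(feat, (n, -1))
        pieces.append(nn.mul(flat, np.float32(w / flat.shape[1])))
    return CriticSignature(nn.concat(pieces, axis=1), len(feats))


def multiscale_l1(a: CriticSignature, b: CriticSignature) -> nn.Tensor:
    """Signature distance: batch-averaged L1 over the weighted signature,
    normalized by the number of critic stages (i.e. the average over scales
    of the per-scale weighted mean absolute difference)."""
    if a.vector.shape != b.vector.shape:
        raise ValueError("signatures have different shapes")
    n = a.vector.shape[0]
    diff = nn.abs_(nn.sub(a.vector, b.vector))
    return nn.div(nn.sum_(diff), np.float32(n * a.n_layers))
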