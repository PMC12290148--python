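"""The segmentation generator: a U-shaped encoder-decoder with multi-scale
blocks, an input image pyramid, and four deeply supervised heads.

Encoder: level 1 is a cascade-dilated-convolution block, levels 2-5 are
multi-scale feature extraction blocks; 2x2 average pooling halves the
resolution between levels. When the image pyramid is enabled, the input
average-pooled to 1/2, 1/4 and 1/8 resolution is channel-concatenated into
the inputs of levels 2, 3 and 4, compensating for information lost to
downsampling (relevant for low-resolution scintigrams).

Decoder: four stages of bilinear x2 upsampling, concatenation with the
same-resolution encoder output, and a residual multi-scale block. Each of
the three intermediate stages carries an auxiliary head (1x1 conv to one
channel, bilinear resize to the input size, sigmoid); the final stage's head
is a 1x1 conv + sigmoid at full resolution. All heads emit probability maps
in [0, 1] at the input resolution, so a single loss can supervise every
decoding depth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .blocks import BlockConfig, make_decoder_block, make_encoder_block
from .data_io import LesionMask, Scintigram
from .errors import ConfigurationError

__all__ = ["GeneratorConfig", "SegOutputs", "Generator", "build_generator",
           "normalize_image", "predict_mask", "save_checkpoint", "load_checkpoint"]


@dataclass
class GeneratorConfig:
    levels: int = 5
    base_channels: int = 64
    use_pyramid: bool = True
    use_deep_supervision: bool = True
    encoder_block_types: tuple[str, ...] = ("cdc", "msfe", "msfe", "msfe", "msfe")
    decoder_block_type: str = "rms"
    input_normalization: str = "per_image_max"  # or "fixed_16bit"
    norm: str = "batch"
    block: BlockConfig = field(default_factory=BlockConfig)
    seed: int = 42

    def __post_init__(self):
        if self.levels < 2:
            raise ConfigurationError("generator needs at least 2 levels")
        if len(self.encoder_block_types) != self.levels:
            raise ConfigurationError(
                f"encoder_block_types must list {self.levels} kinds, "
                f"got {len(self.encoder_block_types)}")
        if self.input_normalization not in ("per_image_max", "fixed_16bit"):
            raise ConfigurationError(
                f"unknown input_normalization {self.input_normalization!r}")


@dataclass
class SegOutputs:
    """Per-head probability maps, ordered deepest decoder stage first.

    ``heads[-1]`` is the full-resolution final prediction used at inference.
    """
    heads: list

    @property
    def final(self):
        return self.heads[-1]

    def __len__(self):
        return len(self.heads)


class Generator(nn.Module):
    def __init__(self, cfg: GeneratorConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        L = cfg.levels
        ch = [cfg.base_channels * 2 ** i for i in range(L)]
        self.channels = ch

        # encoder; pyramid images add one input channel at levels 2..4
        self.encoders = []
        in_ch = 1
        for lvl in range(L):
            extra = 1 if (cfg.use_pyramid and 1 <= lvl <= 3) else 0
            self.encoders.append(make_encoder_block(
                cfg.encoder_block_types[lvl], in_ch + extra, ch[lvl],
                cfg.block, cfg.norm, rng))
            in_ch = ch[lvl]

        # decoder: L-1 stages from the bottleneck back to full resolution
        self.decoders = []
        self.head_convs = []
        for lvl in range(L - 2, -1, -1):
            self.decoders.append(make_decoder_block(
                cfg.decoder_block_type, ch[lvl + 1] + ch[lvl], ch[lvl],
                cfg.block, cfg.norm, rng))
            self.head_convs.append(nn.Conv2d(ch[lvl], 1, 1, rng=rng))

    # ------------------------------------------------------------------
    def forward(self, x: nn.Tensor) -> SegOutputs:
        n, c, h, w = x.shape
        factor = 2 ** (self.cfg.levels - 1)
        if h % factor or w % factor:
            raise ValueError(
                f"input spatial dims ({h},{w}) must be divisible by {factor} "
                f"for a {self.cfg.levels}-level generator")

        # pyramid of the (already normalized) input image
        pyramid = []
        if self.cfg.use_pyramid:
            p = x
            for _ in range(3):
                p = nn.avg_pool2d(p, 2)
                pyramid.append(p)

        skips = []
        feat = x
        for lvl, enc in enumerate(self.encoders):
            if lvl > 0:
                feat = nn.avg_pool2d(feat, 2)
                if self.cfg.use_pyramid and lvl <= 3:
                    feat = nn.concat([feat, pyramid[lvl - 1]], axis=1)
            feat = enc(feat)
            if lvl < len(self.encoders) - 1:
                skips.append(feat)

        heads = []
        n_stages = len(self.decoders)
        for i, (dec, head) in enumerate(zip(self.decoders, self.head_convs)):
            skip = skips[-(i + 1)]
            feat = nn.bilinear_resize(feat, skip.shape[2:])
            feat = dec(nn.concat([feat, skip], axis=1))
            is_last = i == n_stages - 1
            if is_last:
                heads.append(nn.sigmoid(head(feat)))
            elif self.cfg.use_deep_supervision:
                logits = nn.bilinear_resize(head(feat), (h, w))
                heads.append(nn.sigmoid(logits))
        return SegOutputs(heads)


def build_generator(cfg: GeneratorConfig) -> Generator:
    return Generator(cfg)


def normalize_image(pixels: np.ndarray, mode: str = "per_image_max") -> np.ndarray:
    """Map integer counts to [0, 1] floats for the networks.

    ``per_image_max`` divides by the image's own maximum count (tracer uptake
    varies widely between patients, so a per-image scale uses the full
    dynamic range); ``fixed_16bit`` divides by 65535.
    """
    px = np.asarray(pixels, dtype=np.float32)
    if mode == "per_image_max":
        m = px.max()
        return px / m if m > 0 else np.zeros_like(px)
    if mode == "fixed_16bit":
        return px / np.float32(np.iinfo(np.uint16).max)
    raise ConfigurationError(f"unknown normalization mode {mode!r}")


def predict_mask(model: Generator, image: Scintigram,
                 threshold: float = 0.5) -> LesionMask:
    """Binarize the final head at >= threshold (0.5-valued pixels count as
    foreground)."""
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(f"threshold must be in (0,1), got {threshold}")
    model.eval()
    x = normalize_image(image.pixels, model.cfg.input_normalization)
    out = model(nn.Tensor(x[None, None]))
    prob = out.final.data[0, 0]
    return LesionMask((prob >= threshold).astype(np.uint8))


# ---------------------------------------------------------------------------
# checkpointing: weights + embedded config in a single npz file
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: Generator,
                    extra_state: dict | None = None) -> None:
    cfg = asdict(model.cfg)
    payload = {"__config__": np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8)}
    for key, value in model.state_dict().items():
        payload["w:" + key] = value
    if extra_state:
        for key, value in extra_state.items():
            payload["x:" + key] = value
    np.savez(Path(path), **payload)


def load_checkpoint(path: str | Path) -> Generator:
    with np.load(Path(path)) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["block"] = BlockConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in cfg_dict["block"].items()})
        for key in ("encoder_block_types",):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = GeneratorConfig(**cfg_dict)
        model = Generator(cfg)
        state = {k[2:]: data[k] for k in data.files if k.startswith("w:")}
        model.load_state_dict(state)
    return model
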