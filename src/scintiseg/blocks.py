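"""Architectural building blocks and receptive-field arithmetic.

The segmentation generator is assembled from four kinds of blocks, all
spatial-shape preserving (stride 1, padding = dilation for 3x3 kernels):

* ``CDCBlock``  -- cascade of six dilated 3x3 conv-norm-ReLU units with
  dilation rates cycling 1,2,4,1,2,4. The cycling schedule follows the
  hybrid-dilated-convolution rule, which avoids the gridding artifact of
  naive dilation stacks while growing the receptive field to 29x29 pixels.
* ``CRACBlock`` -- the same cascade with two additive residual skips: the
  block input is added after unit 3, and the input of unit 4 is added after
  unit 6.
* ``RFBBlock``  -- an Inception-style receptive-field block with three
  parallel branches of equivalent kernel size 1, 3 and 5, each followed by a
  3x3 dilated conv (rates 1, 3, 5), summed with a residual path and the CRAC
  output and passed through a ReLU.
* ``MSFEBlock`` -- the composition RFB(x, CRAC(x)), the multi-scale feature
  extractor used at encoder levels 2-5.
* ``RMSBlock``  -- the residual multi-scale decoder block: three dilated
  conv units (rates 1, 2, 4) with a skip from unit 1's output to the sum
  after unit 3.

``receptive_field_sequence`` implements the cumulative receptive-field
recursion for a stack of conv layers: with the input counting as the first
stage (rf = 1), a layer with kernel ``ks``, stride ``s`` and dilation ``d``
contributes rf = ks + (ks-1)(d-1) + s*(rf_prev - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError

__all__ = [
    "ConvLayerSpec", "BlockConfig", "receptive_field_sequence",
    "ConvUnit", "CDCBlock", "CRACBlock", "RFBBlock", "MSFEBlock",
    "RMSBlock", "PlainDoubleBlock", "make_encoder_block", "make_decoder_block",
]


@dataclass(frozen=True)
class ConvLayerSpec:
    """Geometry of one conv layer: kernel, stride, padding, dilation."""
    ks: int
    s: int = 1
    p: int = 0
    d: int = 1

    def __post_init__(self):
        if self.ks < 1 or self.ks % 2 == 0:
            raise ConfigurationError(f"kernel size must be odd and >= 1, got {self.ks}")
        if self.s < 1 or self.d < 1 or self.p < 0:
            raise ConfigurationError(
                f"invalid layer spec (s={self.s}, d={self.d}, p={self.p})")


@dataclass
class BlockConfig:
    """Dilation schedules for the composite blocks."""
    in_channels: int = 64
    out_channels: int = 64
    crac_dilations: tuple[int, ...] = (1, 2, 4, 1, 2, 4)
    rms_dilations: tuple[int, ...] = (1, 2, 4)
    rfb_branch_dilations: tuple[int, ...] = (1, 3, 5)


def receptive_field_sequence(stack: list[ConvLayerSpec]) -> list[int]:
    """Cumulative receptive field after each layer of a conv stack.

    Returns one value per layer; for the canonical six-layer cascade
    (ks=3, s=1, d=1,2,4,1,2,4) the sequence is [3, 7, 15, 17, 21, 29].
    """
    if not stack:
        raise ConfigurationError("receptive_field_sequence: empty stack")
    rf = 1  # the input pixel itself
    out = []
    for spec in stack:
        rf = spec.ks + (spec.ks - 1) * (spec.d - 1) + spec.s * (rf - 1)
        out.append(rf)
    return out


class ConvUnit(nn.Module):
    """conv -> norm -> ReLU with padding = dilation * (ks-1)/2 (shape preserving)."""

    def __init__(self, in_ch: int, out_ch: int, ks: int = 3, dilation: int = 1,
                 norm: str = "batch", act: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        pad = dilation * (ks - 1) // 2
        self.conv = nn.Conv2d(in_ch, out_ch, ks, padding=pad, dilation=dilation,
                              rng=rng)
        self.norm = nn.make_norm(norm, out_ch)
        self.act = nn.ReLU() if act else nn.Identity()

    def forward(self, x):
        return self.act(self.norm(self.conv(x)))


def _projection(in_ch: int, out_ch: int, rng) -> nn.Module:
    """Identity skip when channel counts agree, 1x1 projection otherwise."""
    if in_ch == out_ch:
        return nn.Identity()
    return nn.Conv2d(in_ch, out_ch, 1, rng=rng)


class CDCBlock(nn.Module):
    """Cascade dilated convolution: six conv units, dilations cycling 1,2,4."""

    def __init__(self, in_ch: int, out_ch: int,
                 dilations: tuple[int, ...] = (1, 2, 4, 1, 2, 4),
                 norm: str = "batch", rng: np.random.Generator | None = None):
        super().__init__()
        if len(dilations) != 6:
            raise ConfigurationError(f"CDC expects 6 dilation rates, got {len(dilations)}")
        chans = [in_ch] + [out_ch] * 6
        self.units = [ConvUnit(chans[i], chans[i + 1], 3, dilations[i],
                               norm=norm, rng=rng) for i in range(6)]

    def forward(self, x):
        for u in self.units:
            x = u(x)
        return x

    def layer_specs(self) -> list[ConvLayerSpec]:
        return [ConvLayerSpec(3, 1, u.conv.padding, u.conv.dilation)
                for u in self.units]


class CRACBlock(nn.Module):
    """CDC cascade plus residual skips: input -> after unit 3, unit-4 input -> after unit 6."""

    def __init__(self, in_ch: int, out_ch: int,
                 dilations: tuple[int, ...] = (1, 2, 4, 1, 2, 4),
                 norm: str = "batch", rng: np.random.Generator | None = None):
        super().__init__()
        if len(dilations) != 6:
            raise ConfigurationError(f"CRAC expects 6 dilation rates, got {len(dilations)}")
        chans = [in_ch] + [out_ch] * 6
        self.units = [ConvUnit(chans[i], chans[i + 1], 3, dilations[i],
                               norm=norm, rng=rng) for i in range(6)]
        self.skip1 = _projection(in_ch, out_ch, rng)

    def forward(self, x):
        h = x
        for u in self.units[:3]:
            h = u(h)
        h = h + self.skip1(x)          # first residual: block input -> unit-3 output
        mid = h
        for u in self.units[3:]:
            h = u(h)
        return h + mid                 # second residual: unit-4 input -> unit-6 output

    def layer_specs(self) -> list[ConvLayerSpec]:
        return [ConvLayerSpec(3, 1, u.conv.padding, u.conv.dilation)
                for u in self.units]


class RFBBlock(nn.Module):
    """Receptive-field block: parallel branches with equivalent kernels 1, 3, 5.

    Branch compositions (each "conv" is conv-norm-ReLU):
      branch 1: 1x1
      branch 2: 1x1 then 3x3
      branch 3: 1x1 then two stacked 3x3 (equivalent 5x5)
    Each branch is followed by a 3x3 dilated conv with the branch's dilation
    rate (padding = rate). Branch sums, a residual path from the input, and
    the CRAC output are added elementwise and passed through a ReLU.
    """

    def __init__(self, in_ch: int, out_ch: int,
                 branch_dilations: tuple[int, ...] = (1, 3, 5),
                 norm: str = "batch", rng: np.random.Generator | None = None):
        super().__init__()
        if len(branch_dilations) != 3:
            raise ConfigurationError("RFB expects 3 branch dilation rates")
        d1, d2, d3 = branch_dilations
        self.branch1 = nn.Sequential(
            ConvUnit(in_ch, out_ch, 1, norm=norm, rng=rng),
            ConvUnit(out_ch, out_ch, 3, dilation=d1, norm=norm, rng=rng))
        self.branch2 = nn.Sequential(
            ConvUnit(in_ch, out_ch, 1, norm=norm, rng=rng),
            ConvUnit(out_ch, out_ch, 3, norm=norm, rng=rng),
            ConvUnit(out_ch, out_ch, 3, dilation=d2, norm=norm, rng=rng))
        self.branch3 = nn.Sequential(
            ConvUnit(in_ch, out_ch, 1, norm=norm, rng=rng),
            ConvUnit(out_ch, out_ch, 3, norm=norm, rng=rng),
            ConvUnit(out_ch, out_ch, 3, norm=norm, rng=rng),
            ConvUnit(out_ch, out_ch, 3, dilation=d3, norm=norm, rng=rng))
        self.residual = _projection(in_ch, out_ch, rng)

    def forward(self, x, crac_out):
        if x.shape[2:] != crac_out.shape[2:]:
            raise ValueError(
                f"RFB: input {x.shape[2:]} and CRAC output {crac_out.shape[2:]} "
                "must share spatial dims")
        s = self.branch1(x) + self.branch2(x) + self.branch3(x)
        return nn.relu(s + self.residual(x) + crac_out)

    @staticmethod
    def branch_equivalent_kernels() -> list[int]:
        """Equivalent kernel of each branch's pre-dilation composition."""
        specs = {
            1: [ConvLayerSpec(1)],
            2: [ConvLayerSpec(1), ConvLayerSpec(3, p=1)],
            3: [ConvLayerSpec(1), ConvLayerSpec(3, p=1), ConvLayerSpec(3, p=1)],
        }
        return [receptive_field_sequence(specs[b])[-1] for b in (1, 2, 3)]


class MSFEBlock(nn.Module):
    """Multi-scale feature extraction: RFB applied to (x, CRAC(x))."""

    def __init__(self, in_ch: int, out_ch: int,
                 crac_dilations: tuple[int, ...] = (1, 2, 4, 1, 2, 4),
                 rfb_branch_dilations: tuple[int, ...] = (1, 3, 5),
                 norm: str = "batch", rng: np.random.Generator | None = None):
        super().__init__()
        self.crac = CRACBlock(in_ch, out_ch, crac_dilations, norm=norm, rng=rng)
        self.rfb = RFBBlock(in_ch, out_ch, rfb_branch_dilations, norm=norm, rng=rng)

    def forward(self, x):
        return self.rfb(x, self.crac(x))


class RMSBlock(nn.Module):
    """Residual multi-scale decoder block: 3 dilated units, skip 1 -> after 3."""

    def __init__(self, in_ch: int, out_ch: int,
                 dilations: tuple[int, ...] = (1, 2, 4),
                 norm: str = "batch", rng: np.random.Generator | None = None):
        super().__init__()
        if len(dilations) != 3:
            raise ConfigurationError(f"RMS expects 3 dilation rates, got {len(dilations)}")
        self.unit1 = ConvUnit(in_ch, out_ch, 3, dilations[0], norm=norm, rng=rng)
        self.unit2 = ConvUnit(out_ch, out_ch, 3, dilations[1], norm=norm, rng=rng)
        self.unit3 = ConvUnit(out_ch, out_ch, 3, dilations[2], norm=norm, rng=rng)

    def forward(self, x):
        h1 = self.unit1(x)
        return self.unit3(self.unit2(h1)) + h1

    def layer_specs(self) -> list[ConvLayerSpec]:
        return [ConvLayerSpec(3, 1, u.conv.padding, u.conv.dilation)
                for u in (self.unit1, self.unit2, self.unit3)]


class PlainDoubleBlock(nn.Module):
    """Two plain 3x3 conv units; the non-multi-scale fallback for ablations."""

    def __init__(self, in_ch: int, out_ch: int, norm: str = "batch",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.unit1 = ConvUnit(in_ch, out_ch, 3, norm=norm, rng=rng)
        self.unit2 = ConvUnit(out_ch, out_ch, 3, norm=norm, rng=rng)

    def forward(self, x):
        return self.unit2(self.unit1(x))


def make_encoder_block(kind: str, in_ch: int, out_ch: int, cfg: BlockConfig,
                       norm: str, rng) -> nn.Module:
    if kind == "cdc":
        return CDCBlock(in_ch, out_ch, cfg.crac_dilations, norm=norm, rng=rng)
    if kind == "msfe":
        return MSFEBlock(in_ch, out_ch, cfg.crac_dilations,
                         cfg.rfb_branch_dilations, norm=norm, rng=rng)
    if kind == "plain":
        return PlainDoubleBlock(in_ch, out_ch, norm=norm, rng=rng)
    raise ConfigurationError(f"unknown encoder block kind {kind!r}")


def make_decoder_block(kind: str, in_ch: int, out_ch: int, cfg: BlockConfig,
                       norm: str, rng) -> nn.Module:
    if kind == "rms":
        return RMSBlock(in_ch, out_ch, cfg.rms_dilations, norm=norm, rng=rng)
    if kind == "plain":
        return PlainDoubleBlock(in_ch, out_ch, norm=norm, rng=rng)
    raise ConfigurationError(f"unknown decoder block kind {kind!r}")
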