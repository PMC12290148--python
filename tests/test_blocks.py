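"""Block contracts: receptive-field arithmetic vs an empirical
gradient-footprint oracle, shape preservation, and residual identities."""

import numpy as np
import pytest

from scintiseg import nn
from scintiseg.blocks import (CDCBlock, ConvLayerSpec, CRACBlock, MSFEBlock,
                              PlainDoubleBlock, RFBBlock, RMSBlock,
                              receptive_field_sequence)

CASCADE_SCHEDULES = [  # the five dilation schedules of the cascade ablation
    (1, 1, 1, 1, 1, 1),
    (1, 2, 3, 1, 2, 3),
    (1, 2, 4, 1, 2, 4),
    (1, 3, 5, 1, 3, 5),
    (1, 5, 7, 1, 5, 7),
]


def _linearize(block):
    """All-positive weights + zero bias: ReLU passes everything, so the
    nonzero input-gradient support IS the receptive field."""
    for _, p in block.named_parameters():
        p.data = np.abs(p.data) + np.float32(0.01)
        if p.data.ndim == 1:  # biases/norm params don't carry support
            p.data = np.zeros_like(p.data)
    return block


def empirical_footprint(block, in_ch=1, size=64):
    """Width of the input region influencing the center output pixel."""
    x = nn.Tensor(np.ones((1, in_ch, size, size), np.float32), requires_grad=True)
    out = block(x)
    seed = np.zeros_like(out.data)
    seed[0, 0, size // 2, size // 2] = 1.0
    out.backward(seed)
    support = np.abs(x.grad[0]).max(axis=0) > 1e-12
    rows = np.flatnonzero(support.any(axis=1))
    cols = np.flatnonzero(support.any(axis=0))
    height = rows[-1] - rows[0] + 1
    width = cols[-1] - cols[0] + 1
    assert height == width, "dilated 3x3 stacks have square footprints"
    return int(width)


def test_receptive_field_sequence_of_canonical_cascade():
    """Six dilated 3x3 layers with rates 1,2,4,1,2,4 see 3,7,15,17,21,29 px."""
    specs = [ConvLayerSpec(3, 1, d, d) for d in (1, 2, 4, 1, 2, 4)]
    assert receptive_field_sequence(specs) == [3, 7, 15, 17, 21, 29]


def test_receptive_field_edge_cases():
    assert receptive_field_sequence([ConvLayerSpec(1)]) == [1]
    undilated = [ConvLayerSpec(3, 1, 1, 1)] * 6
    assert receptive_field_sequence(undilated) == [3, 5, 7, 9, 11, 13]


@pytest.mark.parametrize("dilations", CASCADE_SCHEDULES)
def test_analytic_rf_equals_gradient_footprint(dilations):
    """The recursion and the empirical footprint agree on every schedule."""
    specs = [ConvLayerSpec(3, 1, d, d) for d in dilations]
    analytic = receptive_field_sequence(specs)[-1]
    block = _linearize(CDCBlock(1, 1, dilations, norm="none",
                                rng=np.random.default_rng(0)))
    assert empirical_footprint(block) == analytic


def test_crac_footprint_not_smaller_than_cdc():
    rngs = (np.random.default_rng(0), np.random.default_rng(0))
    cdc = _linearize(CDCBlock(1, 1, norm="none", rng=rngs[0]))
    crac = _linearize(CRACBlock(1, 1, norm="none", rng=rngs[1]))
    assert empirical_footprint(crac) >= empirical_footprint(cdc)


def test_msfe_footprint_exceeds_plain_double_conv():
    msfe = _linearize(MSFEBlock(1, 1, norm="none", rng=np.random.default_rng(0)))
    plain = _linearize(PlainDoubleBlock(1, 1, norm="none",
                                        rng=np.random.default_rng(0)))
    assert empirical_footprint(msfe) > empirical_footprint(plain) == 5


def test_rms_layer_specs_receptive_fields():
    block = RMSBlock(1, 1, rng=np.random.default_rng(0))
    assert receptive_field_sequence(block.layer_specs()) == [3, 7, 15]


def test_rfb_branch_equivalent_kernels():
    assert RFBBlock.branch_equivalent_kernels() == [1, 3, 5]


@pytest.mark.parametrize("make", [
    lambda rng: CDCBlock(3, 5, rng=rng),
    lambda rng: CRACBlock(3, 5, rng=rng),
    lambda rng: MSFEBlock(3, 5, rng=rng),
    lambda rng: RMSBlock(3, 5, rng=rng),
    lambda rng: PlainDoubleBlock(3, 5, rng=rng),
])
@pytest.mark.parametrize("shape", [(7, 9), (16, 16), (5, 21)])
def test_blocks_preserve_spatial_shape(make, shape, rng):
    block = make(np.random.default_rng(3))
    block.eval()
    x = nn.Tensor(rng.normal(size=(2, 3, *shape)).astype(np.float32))
    out = block(x)
    assert out.shape == (2, 5, *shape)


@pytest.mark.parametrize("channels", [2, 4])
def test_crac_with_zero_weights_is_identity(channels, rng):
    """Both residual skips chain the input through unchanged."""
    block = CRACBlock(channels, channels, norm="none",
                      rng=np.random.default_rng(0))
    for _, p in block.named_parameters():
        p.data = np.zeros_like(p.data)
    x = rng.normal(size=(1, channels, 6, 6)).astype(np.float32)
    np.testing.assert_array_equal(block(nn.Tensor(x)).data, x)


def test_rfb_zero_branches_reduce_to_relu_of_sum(rng):
    block = RFBBlock(3, 3, norm="none", rng=np.random.default_rng(0))
    for name, p in block.named_parameters():
        if name.startswith("branch"):
            p.data = np.zeros_like(p.data)
    x = rng.normal(size=(1, 3, 6, 6)).astype(np.float32)
    crac_out = rng.normal(size=(1, 3, 6, 6)).astype(np.float32)
    out = block(nn.Tensor(x), nn.Tensor(crac_out)).data
    np.testing.assert_allclose(out, np.maximum(x + crac_out, 0.0), atol=1e-6)


def test_rms_zero_tail_keeps_unit1_output(rng):
    block = RMSBlock(3, 4, norm="none", rng=np.random.default_rng(0))
    for name, p in block.named_parameters():
        if name.startswith(("unit2", "unit3")):
            p.data = np.zeros_like(p.data)
    x = nn.Tensor(rng.normal(size=(1, 3, 6, 6)).astype(np.float32))
    np.testing.assert_allclose(block(x).data, block.unit1(x).data, atol=1e-6)
    assert block(x).data.min() >= 0.0  # unit 1 output is post-ReLU


def test_msfe_is_rfb_of_crac(rng):
    block = MSFEBlock(2, 3, norm="none", rng=np.random.default_rng(0))
    block.eval()
    x = nn.Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32))
    direct = block(x).data
    composed = block.rfb(x, block.crac(x)).data
    np.testing.assert_array_equal(direct, composed)


def test_rfb_rejects_mismatched_crac_shape(rng):
    block = RFBBlock(2, 2, rng=np.random.default_rng(0))
    x = nn.Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32))
    bad = nn.Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32))
    with pytest.raises(ValueError, match="spatial dims"):
        block(x, bad)
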