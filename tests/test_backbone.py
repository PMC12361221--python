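"""Network skeleton: resolution ladders, aggregation contract, booster
behaviour and parameter/FLOP accounting properties."""

import numpy as np
import pytest

from bisenext import nn
from bisenext.backbone import (BGALayer, BiSeNeXt, DetailBranch, FeatureMap,
                               aggregate, build_detail_branch,
                               build_semantic_branch, count_flops, count_parameters)
from bisenext.config import NetworkConfig, PointParams, StageSpec
from bisenext.nn import autograd as A


@pytest.fixture(scope="module")
def tiny_cfg():
    return NetworkConfig(input_size=64, width_mult=0.125, eama_groups=2,
                         point_params=PointParams(j=2, n=32, beta=0.75, m=2))


def test_detail_branch_resolution_ladder(tiny_cfg):
    branch = build_detail_branch(tiny_cfg)
    branch.eval()
    x = A.Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32))
    out, stages = branch(x, return_stages=True)
    assert out.shape == (1, tiny_cfg.detail_widths[-1], 8, 8)          # 1/8
    fractions = sorted({s.shape[2] / 64 for s in stages}, reverse=True)
    assert fractions == [1.0, 0.5, 0.25, 0.125]


def test_semantic_branch_resolution_ladder(tiny_cfg):
    branch = build_semantic_branch(tiny_cfg)
    branch.eval()
    x = A.Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32))
    out, taps = branch(x)
    assert out.shape == (1, tiny_cfg.semantic_widths[-1], 2, 2)        # 1/32
    assert [t.shape[2] for t in taps] == [16, 8, 4, 2]                 # 1/4..1/32
    assert taps[0].shape[1] == tiny_cfg.semantic_widths[0]             # stem width


def test_stem_output_channels_quarter_resolution():
    cfg = NetworkConfig(use_dfeb=False, use_eama=False, use_pointrefine=False)
    branch = build_semantic_branch(cfg)
    branch.eval()
    x = A.Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32))
    out = branch.stem(x)
    assert out.shape == (1, 16, 16, 16)


def test_branches_reject_indivisible_inputs(tiny_cfg):
    d = build_detail_branch(tiny_cfg)
    with pytest.raises(ValueError, match="divisible by 8"):
        d(A.Tensor(np.zeros((1, 3, 60, 64), dtype=np.float32)))
    s = build_semantic_branch(tiny_cfg)
    with pytest.raises(ValueError, match="divisible by 32"):
        s(A.Tensor(np.zeros((1, 3, 48, 48), dtype=np.float32)))


def test_aggregate_contract_and_resolution(rng):
    bga = BGALayer(8, rng=rng)
    bga.eval()
    d = A.Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
    s = A.Tensor(rng.normal(size=(1, 8, 2, 2)).astype(np.float32))
    out = aggregate(FeatureMap(d, 1 / 8), FeatureMap(s, 1 / 32), bga)
    assert out.data.shape == (1, 8, 8, 8) and out.resolution_fraction == 1 / 8
    with pytest.raises(ValueError, match="1/8"):
        aggregate(FeatureMap(d, 1 / 4), FeatureMap(s, 1 / 32), bga)
    with pytest.raises(ValueError, match="1/32"):
        bga(d.data, np.zeros((1, 8, 3, 3), dtype=np.float32))


def test_aggregate_zero_semantic_gates_at_half(rng):
    """Zero semantic input: its sigmoid gate is exactly 0.5 everywhere, so the
    detail path is halved; output is finite and matches the hand-evaluable
    identity-weight formula."""
    bga = BGALayer(2)
    bga.eval()
    # make every conv an identity (centre tap 1) and BN a no-op
    for mod in bga.modules():
        if isinstance(mod, nn.Conv2d):
            mod.weight.data[...] = 0.0
            kh, kw = mod.kernel_size
            for o in range(mod.out_channels):
                mod.weight.data[o, 0 if mod.groups > 1 else o, kh // 2, kw // 2] = 1.0
    d = np.abs(np.random.default_rng(0).normal(size=(1, 2, 8, 8))).astype(np.float32)
    s = np.zeros((1, 2, 2, 2), dtype=np.float32)
    out = bga(A.Tensor(d), A.Tensor(s)).data
    assert np.isfinite(out).all()
    # independent numpy evaluation of the gated sum with identity weights
    bn = 1.0 / np.sqrt(1.0 + 1e-5)
    left = d * bn * 0.5                       # detail x sigmoid(0) gate
    down = d[:, :, ::2, ::2] * bn             # identity stride-2 conv -> 4x4
    pad = np.pad(down, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="constant")
    pooled = np.zeros((1, 2, 2, 2), dtype=np.float32)
    for i in range(2):                        # 3x3 average pool, stride 2
        for j in range(2):
            pooled[0, :, i, j] = pad[0, :, 2 * i:2 * i + 3, 2 * j:2 * j + 3].mean(axis=(1, 2))
    small = pooled * 0.5                      # x sigmoid(0) of semantic side
    up = A.interpolate_bilinear(A.Tensor(small), (8, 8)).data
    expected = np.maximum((left + up) * bn, 0)
    np.testing.assert_allclose(out, expected, rtol=1e-4, atol=1e-6)


def test_forward_contract_and_booster_modes(tiny_cfg):
    net = BiSeNeXt(tiny_cfg, seed=0)
    x = np.zeros((2, 3, 64, 64), dtype=np.float32)
    net.train()
    res = net(x)
    assert res.main_logits.shape == (2, 3, 8, 8)
    assert len(res.aux_logits) == 4
    assert res.fine_features.shape[2:] == (8, 8)
    net.eval()
    res = net(x)
    assert res.aux_logits == []               # booster is train-only
    with pytest.raises(ValueError, match="divisible by 32"):
        net(np.zeros((1, 3, 50, 64), dtype=np.float32))


def test_single_conv_parameter_closed_form():
    conv = nn.Conv2d(4, 8, 3, bias=True)
    assert sum(p.size for p in conv.parameters()) == 4 * 8 * 9 + 8 == 296


def test_detail_branch_hand_counted_toy_config():
    """Two plain conv stages, counted layer by layer by hand."""
    cfg = NetworkConfig(use_dfeb=False, use_eama=False, use_pointrefine=False)
    stages = [StageSpec("Conv", 8, 2), StageSpec("Conv", 8, 1)]
    branch = DetailBranch.__new__(DetailBranch)
    nn.Module.__init__(branch)
    blocks = []
    cin = 3
    for spec in stages:
        blocks.append(DetailBranch._build(spec, cin, cfg, np.random.default_rng(0)))
        cin = spec.c
    branch.blocks = nn.Sequential(*blocks)
    hand = (3 * 8 * 9 + 2 * 8) + (8 * 8 * 9 + 2 * 8)   # convs + BN pairs
    assert branch.num_parameters() == hand == 824


def test_parameter_count_invariant_to_input_size(tiny_cfg):
    net = BiSeNeXt(tiny_cfg, seed=0)
    n0 = count_parameters(net)
    net.eval()
    for size in (32, 64):
        net(np.zeros((1, 3, size, size), dtype=np.float32))
    assert count_parameters(net) == n0
    assert count_parameters(net, include_aux=True) > n0


def test_flops_scale_by_four_when_spatial_dims_double():
    cfg = NetworkConfig(input_size=64, width_mult=0.125, eama_groups=2,
                        use_pointrefine=False)
    net = BiSeNeXt(cfg, seed=0)
    f64 = count_flops(net, 64)
    f128 = count_flops(net, 128)
    # conv costs are quadratic in image size; the only deviations are the
    # constant-cost global-pool conv (context embedding) and the linear-cost
    # directional-pool convs (attention), together < 0.1% of the total
    assert f128 == pytest.approx(4 * f64, rel=1e-3)


def test_booster_heads_untouched_in_eval_flop_count():
    """Evaluation cost is identical with and without the aux heads present."""
    cfg = NetworkConfig(input_size=64, width_mult=0.125, eama_groups=2,
                        use_pointrefine=False)
    net = BiSeNeXt(cfg, seed=0)
    baseline = count_flops(net, 64)
    for p in net.aux_heads.parameters():
        p.data[...] = 1e9                      # poison: any use would explode
    out = net.predict_logits(np.zeros((1, 3, 64, 64), dtype=np.float32))
    assert np.isfinite(out).all()
    assert count_flops(net, 64) == baseline
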