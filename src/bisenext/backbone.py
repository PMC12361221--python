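"""BiSeNeXt network skeleton.

Two parallel encoders: a *detail branch* that keeps high resolution
(output at 1/8 of the input) and a *semantic branch* that downsamples
aggressively to 1/32 through a Stem, gather-and-expansion (GE) layers and a
context-embedding (CE) block.  A bilateral guided aggregation (BGA) layer
fuses them — each branch gates the other through a sigmoid after resolution
alignment — and a segmentation head emits class logits at 1/8 resolution.
Training adds booster heads on intermediate semantic stages; they are never
touched in evaluation mode, so inference cost is unchanged.

The detail branch comes in two flavours: plain strided 3x3 conv stages
(the original bilateral-network baseline) or DFEB stages with optional EAMA
attention.  The decoder is either a dense head (1024 mid channels, bilinear
upsampling) or a light coarse head feeding the PointRefine decoder.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from . import nn
from .config import NetworkConfig, StageSpec
from .dfeb import DFEB
from .eama import EAMA
from .nn import autograd as A
from .pointrefine import PointHead, refine


class FeatureMap(NamedTuple):
    """A dense activation map plus its resolution relative to the input."""

    data: A.Tensor
    resolution_fraction: float


class ForwardResult(NamedTuple):
    main_logits: A.Tensor        # (B, K, H/8, W/8)
    aux_logits: list             # one entry per boosted stage (training only)
    fine_features: A.Tensor      # final detail-branch features, 1/8 resolution


# ---------------------------------------------------------------------------
# semantic-branch building blocks (original bilateral-network design)
# ---------------------------------------------------------------------------

class StemBlock(nn.Module):
    def __init__(self, cout: int, rng=None):
        super().__init__()
        self.conv = nn.ConvBNReLU(3, cout, 3, stride=2, rng=rng)
        self.left1 = nn.ConvBNReLU(cout, max(1, cout // 2), 1, rng=rng)
        self.left2 = nn.ConvBNReLU(max(1, cout // 2), cout, 3, stride=2, rng=rng)
        self.fuse = nn.ConvBNReLU(2 * cout, cout, 3, rng=rng)

    def forward(self, x):
        x = self.conv(x)
        left = self.left2(self.left1(x))
        right = A.max_pool2d(x, 3, 2, 1)
        return self.fuse(A.concat([left, right], axis=1))


class GELayer(nn.Module):
    """Gather-and-expansion layer: 3x3 conv, depthwise expansion (factor e),
    1x1 projection; stride 2 uses two depthwise stages and a depthwise+1x1
    shortcut."""

    def __init__(self, cin: int, cout: int, e: int = 6, stride: int = 1, rng=None):
        super().__init__()
        mid = e * cin
        self.stride = stride
        self.conv1 = nn.ConvBNReLU(cin, cin, 3, rng=rng)
        if stride == 1:
            self.dw = nn.ConvBNReLU(cin, mid, 3, groups=cin, act=False, rng=rng)
        else:
            self.dw = nn.Sequential(
                nn.ConvBNReLU(cin, mid, 3, stride=2, groups=cin, act=False, rng=rng),
                nn.ConvBNReLU(mid, mid, 3, groups=mid, act=False, rng=rng))
            self.shortcut = nn.Sequential(
                nn.ConvBNReLU(cin, cin, 3, stride=2, groups=cin, act=False, rng=rng),
                nn.ConvBNReLU(cin, cout, 1, act=False, rng=rng))
        self.proj = nn.ConvBNReLU(mid, cout, 1, act=False, rng=rng)
        self.identity = stride == 1 and cin == cout

    def forward(self, x):
        out = self.proj(self.dw(self.conv1(x)))
        if self.stride == 2:
            out = out + self.shortcut(x)
        elif self.identity:
            out = out + x
        return A.relu(out)


class CEBlock(nn.Module):
    """Context embedding: BN-ed global pooling re-injected through a 1x1
    conv, then a 3x3 conv."""

    def __init__(self, c: int, rng=None):
        super().__init__()
        self.bn = nn.BatchNorm2d(c)
        self.conv_gap = nn.ConvBNReLU(c, c, 1, rng=rng)
        self.conv_last = nn.ConvBNReLU(c, c, 3, rng=rng)

    def forward(self, x):
        gap = A.reduce_mean(x, axis=(2, 3), keepdims=True)
        feat = self.conv_gap(self.bn(gap))
        return self.conv_last(feat + x)


class BGALayer(nn.Module):
    """Bilateral guided aggregation of detail (1/8) and semantic (1/32) maps."""

    def __init__(self, c: int, rng=None):
        super().__init__()
        self.detail_dw = nn.ConvBNReLU(c, c, 3, groups=c, act=False, rng=rng)
        self.detail_pw = nn.Conv2d(c, c, 1, bias=False, rng=rng)
        self.detail_down = nn.ConvBNReLU(c, c, 3, stride=2, act=False, rng=rng)
        self.semantic_conv = nn.ConvBNReLU(c, c, 3, act=False, rng=rng)
        self.semantic_dw = nn.ConvBNReLU(c, c, 3, groups=c, act=False, rng=rng)
        self.semantic_pw = nn.Conv2d(c, c, 1, bias=False, rng=rng)
        self.out_conv = nn.ConvBNReLU(c, c, 3, rng=rng)

    def forward(self, detail, semantic):
        detail, semantic = A.as_tensor(detail), A.as_tensor(semantic)
        if (detail.shape[2] != 4 * semantic.shape[2]
                or detail.shape[3] != 4 * semantic.shape[3]):
            raise ValueError(
                "aggregation expects the detail map at 1/8 and the semantic map "
                f"at 1/32 of the input; got {detail.shape[2:]} vs {semantic.shape[2:]}")
        size8 = (detail.shape[2], detail.shape[3])
        left = self.detail_pw(self.detail_dw(detail))
        left_down = A.avg_pool2d(self.detail_down(detail), 3, 2, 1)
        right = A.interpolate_bilinear(self.semantic_conv(semantic), size8)
        left = left * A.sigmoid(right)
        small = left_down * A.sigmoid(self.semantic_pw(self.semantic_dw(semantic)))
        return self.out_conv(left + A.interpolate_bilinear(small, size8))


class SegmentHead(nn.Module):
    """3x3 conv (mid channels) + 1x1 classifier; upsampling is the caller's."""

    def __init__(self, cin: int, mid: int, num_classes: int, rng=None):
        super().__init__()
        self.conv = nn.ConvBNReLU(cin, mid, 3, rng=rng)
        self.cls = nn.Conv2d(mid, num_classes, 1, bias=True, rng=rng)

    def forward(self, x):
        return self.cls(self.conv(x))


# ---------------------------------------------------------------------------
# branches
# ---------------------------------------------------------------------------

def _check_divisible(shape, div: int) -> None:
    H, W = shape[-2:]
    if H % div or W % div:
        raise ValueError(f"input spatial size {H}x{W} must be divisible by {div}")


class DetailBranch(nn.Module):
    """Fine-grained spatial encoder; output at 1/8 of the input resolution."""

    def __init__(self, config: NetworkConfig, rng=None):
        super().__init__()
        blocks: list[nn.Module] = []
        cin = 3
        for spec in config.detail_stages:
            for _ in range(spec.r):
                blocks.append(self._build(spec, cin, config, rng))
                cin = spec.c
        self.blocks = nn.Sequential(*blocks)
        self.out_channels = cin

    @staticmethod
    def _build(spec: StageSpec, cin: int, config: NetworkConfig, rng) -> nn.Module:
        if spec.opr == "DFEB":
            return DFEB(cin, spec.c, stride=spec.s, rng=rng)
        if spec.opr == "EAMA":
            # largest group count that divides the width (reduced-width
            # configurations shrink channels below the full-scale group count)
            groups = max(g for g in range(1, config.eama_groups + 1)
                         if spec.c % g == 0)
            return EAMA(spec.c, groups=groups, rng=rng)
        if spec.opr == "Conv":
            return nn.ConvBNReLU(cin, spec.c, 3, stride=spec.s, rng=rng)
        raise ValueError(f"operator {spec.opr!r} not valid in the detail branch")

    def forward(self, x, return_stages: bool = False):
        x = A.as_tensor(x)
        _check_divisible(x.shape, 8)
        stages = []
        for block in self.blocks:
            x = block(x)
            stages.append(x)
        return (x, stages) if return_stages else x


class SemanticBranch(nn.Module):
    """Context encoder: Stem (1/4) -> GE stages (1/8, 1/16, 1/32) -> CE.

    ``forward`` returns the final 1/32 features and the per-resolution stage
    outputs used by the booster heads.
    """

    def __init__(self, config: NetworkConfig, rng=None):
        super().__init__()
        c0, c1, c2, c3 = config.semantic_widths
        self.stem = StemBlock(c0, rng=rng)
        self.stage8 = nn.Sequential(GELayer(c0, c1, 6, 2, rng=rng),
                                    GELayer(c1, c1, 6, 1, rng=rng))
        self.stage16 = nn.Sequential(GELayer(c1, c2, 6, 2, rng=rng),
                                     GELayer(c2, c2, 6, 1, rng=rng))
        self.stage32 = nn.Sequential(GELayer(c2, c3, 6, 2, rng=rng),
                                     *[GELayer(c3, c3, 6, 1, rng=rng) for _ in range(3)])
        self.ce = CEBlock(c3, rng=rng)
        self.tap_channels = (c0, c1, c2, c3)

    def forward(self, x):
        x = A.as_tensor(x)
        _check_divisible(x.shape, 32)
        f4 = self.stem(x)
        f8 = self.stage8(f4)
        f16 = self.stage16(f8)
        f32 = self.stage32(f16)
        return self.ce(f32), [f4, f8, f16, f32]


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

class BiSeNeXt(nn.Module):
    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        super().__init__()
        cfg = config or NetworkConfig()
        rng = np.random.default_rng(seed)
        self.config = cfg
        self.detail = DetailBranch(cfg, rng=rng)
        self.semantic = SemanticBranch(cfg, rng=rng)
        agg_c = cfg.agg_channels
        if self.detail.out_channels != agg_c:
            raise ValueError("detail and semantic branches must meet at equal width")
        self.bga = BGALayer(agg_c, rng=rng)
        mid = cfg.head_mid_point if cfg.use_pointrefine else cfg.head_mid_plain
        self.head = SegmentHead(agg_c, cfg._scale(mid), cfg.num_classes, rng=rng)
        self.aux_heads = nn.Sequential(*[
            SegmentHead(c, cfg._scale(cfg.aux_head_mid), cfg.num_classes, rng=rng)
            for c in self.semantic.tap_channels])
        if cfg.use_pointrefine:
            self.point_head = PointHead(
                agg_c, cfg.num_classes,
                fc_dim=cfg._scale(cfg.point_fc_dim),
                hidden=cfg._scale(cfg.point_mlp_hidden),
                n_hidden=cfg.point_mlp_layers, rng=rng)

    def forward(self, x) -> ForwardResult:
        x = A.as_tensor(x)
        _check_divisible(x.shape, 32)
        fine = self.detail(x)
        sem, taps = self.semantic(x)
        agg = self.bga(fine, sem)
        logits = self.head(agg)
        aux = []
        if self.training:
            aux = [h(t) for h, t in zip(self.aux_heads, taps)]
        return ForwardResult(logits, aux, fine)

    # -- inference ----------------------------------------------------------
    def predict_logits(self, x, rng: np.random.Generator | int = 0) -> np.ndarray:
        """Full-resolution logits: PointRefine when enabled, else bilinear."""
        x = A.as_tensor(x)
        out_size = (x.shape[2], x.shape[3])
        with A.no_grad():
            res = self.forward(x)
            if self.config.use_pointrefine:
                return refine(res.main_logits, res.fine_features, self.point_head,
                              self.config.point_params, rng, out_size)
            return A.interpolate_bilinear(res.main_logits, out_size).data


def aggregate(detail: FeatureMap, semantic: FeatureMap, bga: BGALayer) -> FeatureMap:
    """Contract-checked bilateral aggregation of 1/8 and 1/32 feature maps."""
    if not np.isclose(detail.resolution_fraction, 1 / 8):
        raise ValueError("detail features must be at 1/8 resolution")
    if not np.isclose(semantic.resolution_fraction, 1 / 32):
        raise ValueError("semantic features must be at 1/32 resolution")
    return FeatureMap(bga(detail.data, semantic.data), 1 / 8)


# ---------------------------------------------------------------------------
# profiling
# ---------------------------------------------------------------------------

def count_parameters(net: nn.Module, include_aux: bool = False) -> int:
    """Learnable parameters; booster (aux) heads are excluded by default
    because they carry no inference cost."""
    total = 0
    for name, p in net.named_parameters():
        if not include_aux and name.startswith("aux_heads"):
            continue
        total += p.size
    return total


def count_flops(net: BiSeNeXt, input_size: int | None = None,
                seed: int = 0) -> int:
    """Multiply-accumulates of one eval-mode inference at ``input_size``.

    Counts conv and linear layers only (one MAC = one FLOP), by running an
    instrumented forward pass — including the point decoder when enabled.
    """
    size = input_size or net.config.input_size
    was_training = net.training
    net.eval()
    x = np.zeros((1, 3, size, size), dtype=np.float32)
    counter: dict = {}
    with A.no_grad(), A.count_macs(counter):
        net.predict_logits(x, rng=seed)
    if was_training:
        net.train()
    return counter["macs"]


def profile(net: BiSeNeXt, input_size: int | None = None) -> dict:
    """Params (M) and FLOPs (G, MAC convention) rounded to two decimals."""
    size = input_size or net.config.input_size
    return {
        "params_M": round(count_parameters(net) / 1e6, 2),
        "flops_G": round(count_flops(net, size) / 1e9, 2),
        "input_size": size,
    }


def build_detail_branch(config: NetworkConfig, seed: int = 0) -> DetailBranch:
    return DetailBranch(config, rng=np.random.default_rng(seed))


def build_semantic_branch(config: NetworkConfig, seed: int = 0) -> SemanticBranch:
    return SemanticBranch(config, rng=np.random.default_rng(seed))
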