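"""Dynamic feature extraction block (DFEB).

Two ingredients:

* **DRFConv** — a convolution whose k x k receptive-field contributions are
  re-weighted per position by a softmax attention computed from pooled
  context.  A grouped k x k convolution materialises each receptive field as
  k^2 channels ("sliders"); the attention path pools the input over the same
  windows, mixes channels with a grouped 1 x 1 convolution and normalises the
  k^2 weights of every channel group with a softmax.  The weighted sliders
  are re-tiled into a k-times-enlarged map and collapsed by a k x k
  convolution with stride k, so each output pixel sees exactly one slider.

* **Pixel-shuffle (space-to-depth) downsampling** — a value-conserving
  rearrangement of 2x2 neighbourhoods into channels followed by a 1 x 1
  projection; nothing is discarded, unlike strided convolution or pooling.

``DFEB`` combines them with a convolutional shortcut: the stride-1 variant is
a residual block (DRFConv -> 3x3 conv, plus a 1x1 shortcut), the stride-2
variant sums a strided DRFConv main path with a pixel-shuffle side path.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import autograd as A


def space_to_depth(x, factor: int = 2):
    """Rearrange (B, C, H, W) -> (B, factor^2*C, H/f, W/f).

    Output channel ``c*f^2 + (i*f + j)`` holds the sub-grid ``x[:, c, i::f, j::f]``.
    The input is zero-padded on the right/bottom to a multiple of ``factor``;
    on divisible inputs the rearrangement is a bijection on values.
    """
    if factor < 2:
        raise ValueError("factor must be >= 2")
    x = A.as_tensor(x)
    B, C, H, W = x.shape
    ph = (-H) % factor
    pw = (-W) % factor
    if ph or pw:
        x = A.pad2d(x, (0, ph, 0, pw))
        H, W = H + ph, W + pw
    x = A.reshape(x, (B, C, H // factor, factor, W // factor, factor))
    x = A.transpose(x, (0, 1, 3, 5, 2, 4))
    return A.reshape(x, (B, C * factor * factor, H // factor, W // factor))


def depth_to_space(x, factor: int = 2):
    """Inverse of :func:`space_to_depth` (without removing any padding)."""
    x = A.as_tensor(x)
    B, C, H, W = x.shape
    c = C // (factor * factor)
    x = A.reshape(x, (B, c, factor, factor, H, W))
    x = A.transpose(x, (0, 1, 4, 2, 5, 3))
    return A.reshape(x, (B, c, H * factor, W * factor))


class DRFConv(nn.Module):
    """Dynamic receptive-field convolution.

    in -> grouped kxk conv (C -> k^2 C, "sliders") -> BN -> ReLU, multiplied by
    softmax(grouped 1x1 conv(avg-pooled input)) attention, re-tiled to
    (C, kH', kW') and collapsed with a kxk/stride-k convolution to
    ``out_channels``.  ``stride`` 2 halves resolution (ceiling semantics via
    padding k//2).
    """

    def __init__(self, in_channels: int, out_channels: int, k: int = 3,
                 stride: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        if k < 3 or k % 2 == 0:
            raise ValueError("kernel size must be odd and >= 3")
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.k = k
        self.stride = stride
        self.in_channels = in_channels
        self.out_channels = out_channels
        kk = k * k
        self.slider_conv = nn.Conv2d(in_channels, kk * in_channels, k,
                                     stride=stride, padding=k // 2,
                                     groups=in_channels, bias=False, rng=rng)
        self.norm = nn.BatchNorm2d(kk * in_channels)
        self.att_conv = nn.Conv2d(in_channels, kk * in_channels, 1,
                                  groups=in_channels, bias=False, rng=rng)
        self.out_conv = nn.Conv2d(in_channels, out_channels, k, stride=k,
                                  padding=0, bias=False, rng=rng)

    def attention(self, x):
        """Softmax weights over the k^2 slider positions, shape (B, k^2 C, H', W')."""
        x = A.as_tensor(x)
        k = self.k
        pooled = A.avg_pool2d(x, k, self.stride, padding=k // 2)
        att = self.att_conv(pooled)
        B, _, Hp, Wp = att.shape
        att = A.reshape(att, (B, self.in_channels, k * k, Hp, Wp))
        att = A.softmax(att, axis=2)
        return A.reshape(att, (B, self.in_channels * k * k, Hp, Wp))

    def forward(self, x):
        x = A.as_tensor(x)
        if self.stride == 2 and (x.shape[2] % 2 or x.shape[3] % 2):
            raise ValueError(
                f"stride-2 DRFConv requires even spatial size, got {x.shape[2:]}; "
                "pad the input first")
        k = self.k
        feat = A.relu(self.norm(self.slider_conv(x)))
        weighted = feat * self.attention(x)
        B, _, Hp, Wp = weighted.shape
        # Adjust shape: position-major interleave, one kxk block per slider.
        w = A.reshape(weighted, (B, self.in_channels, k, k, Hp, Wp))
        w = A.transpose(w, (0, 1, 4, 2, 5, 3))           # (B,C,H',k,W',k)
        w = A.reshape(w, (B, self.in_channels, Hp * k, Wp * k))
        return self.out_conv(w)


class PixelShuffleDown(nn.Module):
    """Space-to-depth (factor ``lam``) followed by a 1x1 projection + BN."""

    def __init__(self, in_channels: int, out_channels: int, lam: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.lam = lam
        self.proj = nn.ConvBNReLU(lam * lam * in_channels, out_channels, 1,
                                  act=False, rng=rng)

    def forward(self, x):
        return self.proj(space_to_depth(x, self.lam))


class DFEB(nn.Module):
    """Dynamic feature extraction block (stride 1 or 2).

    stride 1: ReLU( [DRFConv -> BN -> ReLU -> 3x3 ConvBN] + [1x1 ConvBN] )
    stride 2: ReLU( [stride-2 DRFConv -> BN -> ReLU -> 3x3 ConvBN]
                    + [pixel-shuffle down -> 1x1 ConvBN] )
    Odd inputs at stride 2 are zero-padded right/bottom once, identically for
    both branches, giving ceil(H/2) x ceil(W/2) outputs.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.stride = stride
        self.drf = DRFConv(in_channels, out_channels, 3, stride=stride, rng=rng)
        self.drf_bn = nn.BatchNorm2d(out_channels)
        self.conv = nn.ConvBNReLU(out_channels, out_channels, 3, act=False, rng=rng)
        if stride == 1:
            self.shortcut = nn.ConvBNReLU(in_channels, out_channels, 1, act=False, rng=rng)
        else:
            self.shortcut = PixelShuffleDown(in_channels, out_channels, 2, rng=rng)

    def forward(self, x):
        x = A.as_tensor(x)
        if self.stride == 2 and (x.shape[2] % 2 or x.shape[3] % 2):
            x = A.pad2d(x, (0, x.shape[2] % 2, 0, x.shape[3] % 2))
        main = self.conv(A.relu(self.drf_bn(self.drf(x))))
        return A.relu(main + self.shortcut(x))
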