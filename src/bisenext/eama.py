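"""Efficient asymmetric multi-scale attention (EAMA).

Channel-grouped attention: the C channels are split into G groups that are
folded into the batch axis, so all convolutions are tiny (C/G channels) and
shared across groups.  Two parallel branches encode each group:

* a **1x1 branch** — per-row and per-column average pooling produce two 1-D
  profiles that share one 1x1 convolution; their sigmoids gate the group
  (directional "coordinate" attention), followed by group normalisation;
* an **asymmetric branch** — the sum of parallel 1x3, 3x1 and 3x3
  convolutions, capturing multi-scale spatial structure cheaply.

Cross-spatial fusion turns each branch into a spatial map by dotting the
softmax of the *other* branch's globally pooled channel vector with its
flattened features; the sigmoid of the summed maps re-weights the input.
Output shape always equals input shape.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import autograd as A


def directional_pool(x):
    """Per-row and per-column means of (B, C, H, W).

    Returns ``(height_profile, width_profile)`` with shapes (B, C, H) and
    (B, C, W); both average to the same global mean.
    """
    x = A.as_tensor(x)
    return A.reduce_mean(x, axis=3), A.reduce_mean(x, axis=2)


class EAMA(nn.Module):
    def __init__(self, channels: int, groups: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % groups:
            raise ValueError(f"channels ({channels}) must be divisible by groups ({groups})")
        self.channels = channels
        self.groups = groups
        cg = channels // groups
        self.conv1x1 = nn.Conv2d(cg, cg, 1, bias=True, rng=rng)
        self.gn = nn.GroupNorm(cg, cg)
        self.conv1x3 = nn.Conv2d(cg, cg, (1, 3), padding=(0, 1), bias=True, rng=rng)
        self.conv3x1 = nn.Conv2d(cg, cg, (3, 1), padding=(1, 0), bias=True, rng=rng)
        self.conv3x3 = nn.Conv2d(cg, cg, 3, padding=1, bias=True, rng=rng)

    # -- branch pieces (exposed for unit tests) -----------------------------
    def one_by_one_branch(self, gx):
        """Directional pooling -> shared 1x1 conv -> sigmoid gates -> re-weight."""
        Bg, cg, H, W = gx.shape
        zh, zw = directional_pool(gx)                    # (Bg,cg,H), (Bg,cg,W)
        hw = A.concat([A.reshape(zh, (Bg, cg, H, 1)),
                       A.reshape(zw, (Bg, cg, W, 1))], axis=2)
        hw = self.conv1x1(hw)
        xh = hw[:, :, :H, :]                             # (Bg,cg,H,1)
        xw = A.transpose(hw[:, :, H:, :], (0, 1, 3, 2))  # (Bg,cg,1,W)
        return gx * A.sigmoid(xh) * A.sigmoid(xw)

    def asymmetric_branch(self, gx):
        """Sum of parallel 1x3, 3x1 and 3x3 convolutions (shape preserving)."""
        return self.conv1x3(gx) + self.conv3x1(gx) + self.conv3x3(gx)

    def cross_spatial_fuse(self, b1, b2, gx):
        """Sigmoid of two pooled-softmax x flattened-branch dot products."""
        Bg, cg, H, W = gx.shape
        p1 = A.softmax(A.reshape(A.reduce_mean(b1, axis=(2, 3)), (Bg, 1, cg)), axis=2)
        p2 = A.softmax(A.reshape(A.reduce_mean(b2, axis=(2, 3)), (Bg, 1, cg)), axis=2)
        f1 = A.reshape(b1, (Bg, cg, H * W))
        f2 = A.reshape(b2, (Bg, cg, H * W))
        maps = A.matmul(p1, f2) + A.matmul(p2, f1)       # (Bg, 1, H*W)
        weights = A.sigmoid(A.reshape(maps, (Bg, 1, H, W)))
        return gx * weights

    def forward(self, x):
        x = A.as_tensor(x)
        B, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        g = self.groups
        gx = A.reshape(x, (B * g, C // g, H, W))
        gated = self.gn(self.one_by_one_branch(gx))
        asym = self.asymmetric_branch(gx)
        out = self.cross_spatial_fuse(gated, asym, gx)
        return A.reshape(out, (B, C, H, W))
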