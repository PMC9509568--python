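"""Residual attention module (RAM): trunk and mask branches.

The trunk branch is two 3×3 convolutions; the mask branch is a small
hourglass — repeated (3×3 conv, 2×2 max-pool) until the spatial size reaches
the network's minimum output resolution of 7×7, then bilinear ×2 upsampling
with additive skip connections at matching resolutions, a final 1×1
convolution and a sigmoid squashing the mask into [0, 1].  The two branches
combine as ``H = (1 + M) * T``: the mask re-weights trunk features without
ever attenuating them.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import ops


class TrunkBranch(nn.Module):
    """Two successive 3×3 convolutions with an activation between."""

    def __init__(self, channels: int, activation: str = "elu", alpha: float = 1.0):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3, padding=1)
        self.act = nn.Activation(activation, alpha)
        self.conv2 = nn.Conv2d(channels, channels, 3, padding=1)

    def forward(self, x):
        return self.conv2(self.act(self.conv1(x)))


class MaskBranch(nn.Module):
    """Hourglass attention mask; output shape equals input shape, values in [0, 1].

    Built for a fixed square input size so the number of pooling steps (down
    to, never below, 7×7) is known at construction.
    """

    MIN_SIZE = 7

    def __init__(self, channels: int, input_size: int,
                 activation: str = "elu", alpha: float = 1.0):
        super().__init__()
        if input_size < self.MIN_SIZE:
            raise ValueError(f"mask branch input must be at least {self.MIN_SIZE}×{self.MIN_SIZE}")
        self.input_size = int(input_size)
        self.act = nn.Activation(activation, alpha)
        sizes = []
        s = self.input_size
        while s // 2 >= self.MIN_SIZE:
            sizes.append(s)
            s //= 2
        self.skip_sizes = sizes                      # resolutions carrying a conv + skip
        self.n_pool_steps = len(sizes)
        self.encoder = nn.ModuleList(
            nn.Conv2d(channels, channels, 3, padding=1) for _ in sizes)
        self.final = nn.Conv2d(channels, channels, 1)

    def forward(self, x):
        h_in, w_in = x.shape[-2:]
        if h_in < self.MIN_SIZE or w_in < self.MIN_SIZE:
            raise ValueError("mask branch input smaller than 7×7")
        if h_in != self.input_size or w_in != self.input_size:
            raise ValueError(
                f"mask branch built for {self.input_size}×{self.input_size}, got {h_in}×{w_in}")
        skips = []
        h = x
        for conv in self.encoder:
            h = self.act(conv(h))
            skips.append(h)
            h = ops.maxpool2d(h, 2, 2)
        for skip in reversed(skips):
            h = ops.resize_bilinear(h, skip.shape[-2:]) + skip
        return ops.sigmoid(self.final(h))


def attention_combine(trunk, mask):
    """Combination rule ``H = (1 + M) * T`` elementwise; accepts tensors or arrays."""
    t_arr = trunk.data if isinstance(trunk, nn.Tensor) else np.asarray(trunk)
    m_arr = mask.data if isinstance(mask, nn.Tensor) else np.asarray(mask)
    if t_arr.shape != m_arr.shape:
        raise ValueError(f"shape mismatch: trunk {t_arr.shape}, mask {m_arr.shape}")
    if m_arr.min() < -1e-6 or m_arr.max() > 1.0 + 1e-6:
        raise ValueError("mask values must lie in [0, 1]")
    if isinstance(trunk, nn.Tensor) or isinstance(mask, nn.Tensor):
        t = trunk if isinstance(trunk, nn.Tensor) else nn.Tensor(trunk)
        m = mask if isinstance(mask, nn.Tensor) else nn.Tensor(mask)
        return t + m * t
    return (1.0 + m_arr) * t_arr


class ResidualAttention(nn.Module):
    """Full RAM block: ``(1 + mask(x)) * trunk(x)``."""

    def __init__(self, channels: int, input_size: int,
                 activation: str = "elu", alpha: float = 1.0):
        super().__init__()
        self.trunk = TrunkBranch(channels, activation, alpha)
        self.mask = MaskBranch(channels, input_size, activation, alpha)

    def forward(self, x):
        return attention_combine(self.trunk(x), self.mask(x))
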