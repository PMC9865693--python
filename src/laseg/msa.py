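"""Multi-scale feature-fusion attention on skip connections.

Two stages run sequentially on each skip feature map:

*Dual pyramid pooling* — the map is pooled onto 1x1, 2x2, 4x4 and 6x6
grids twice, once with average pooling (context) and once with maximum
pooling (detail).  Each pooled map is projected from C to C/4 channels
with a learned 1x1 convolution and upsampled back.  The four average
maps are stacked to C channels, likewise the four maximum maps, the two
stacks are summed, and the result is concatenated with the input to give
2C channels.

*Dual attention* — position attention reweights every pixel by its
softmax-normalised similarity to every other pixel,

    s_ji = exp(B_i . C_j) / sum_i exp(B_i . C_j)
    E_j  = alpha * sum_i s_ji D_i + A_j,

and channel attention does the same across channels of the raw map,

    x_ji = exp(A_i . A_j) / sum_i exp(A_i . A_j)
    E'_j = beta * sum_i x_ji A_i + A_j.

Both scale parameters start at exactly zero, so a freshly initialised
attention head is the identity; training moves alpha and beta away from
zero only where the similarity structure helps.  The two branch outputs
are combined as the sum of their residual terms on the shared input.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor, concat
from .errors import ConfigurationError, ValidationError

__all__ = ["PyramidPool", "PositionAttention", "ChannelAttention", "MSA"]

_DEFAULT_GRIDS = (1, 2, 4, 6)


class PyramidPool(nn.Module):
    """Dual (average + maximum) pyramid pooling: C -> 2C channels."""

    def __init__(self, channels: int, grids=_DEFAULT_GRIDS, reduction: int = 4,
                 *, rng: np.random.Generator):
        if channels % reduction:
            raise ConfigurationError(
                f"pyramid pooling needs channels divisible by {reduction}, "
                f"got {channels}")
        self.grids = tuple(grids)
        self.channels = channels
        red = channels // reduction
        self.avg_proj = [nn.Conv2d(channels, red, 1, rng=rng) for _ in self.grids]
        self.max_proj = [nn.Conv2d(channels, red, 1, rng=rng) for _ in self.grids]

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValidationError(f"expected {self.channels} channels, got {c}")
        gmax = max(self.grids)
        if h < gmax or w < gmax:
            raise ConfigurationError(
                f"spatial size ({h}, {w}) is smaller than the largest "
                f"pyramid grid {gmax}x{gmax}")
        avg_maps, max_maps = [], []
        for g, proj in zip(self.grids, self.avg_proj):
            p = proj(nn.adaptive_avg_pool2d(x, g))
            avg_maps.append(nn.upsample_bilinear(p, (h, w)))
        for g, proj in zip(self.grids, self.max_proj):
            p = proj(nn.adaptive_max_pool2d(x, g))
            max_maps.append(nn.upsample_bilinear(p, (h, w)))
        fused = concat(avg_maps, axis=1) + concat(max_maps, axis=1)
        return concat([x, fused], axis=1)


class PositionAttention(nn.Module):
    """Spatial self-attention over flattened pixel positions.

    The pairwise map is O((H*W)^2); above ``max_grid`` per side the
    attention is computed on an average-pooled grid and the residual is
    upsampled back, which leaves the alpha=0 identity exact.
    """

    def __init__(self, channels: int, proj_ratio: int = 8, max_grid: int = 32,
                 *, rng: np.random.Generator):
        red = max(1, channels // proj_ratio)
        self.query = nn.Conv2d(channels, red, 1, rng=rng)   # B
        self.key = nn.Conv2d(channels, red, 1, rng=rng)     # C
        self.value = nn.Conv2d(channels, channels, 1, rng=rng)            # D
        self.alpha = Tensor(np.zeros(1, dtype=np.float32), requires_grad=True)
        self.max_grid = max_grid

    def attention_map(self, a: Tensor) -> Tensor:
        """Row-stochastic S of shape (N, H*W, H*W) for the (possibly
        pooled) input."""
        n, c, h, w = a.shape
        b = self.query(a).reshape(n, -1, h * w)             # (N, C', P)
        cmap = self.key(a).reshape(n, -1, h * w)
        energy = cmap.transpose(0, 2, 1) @ b                # e[j, i] = B_i . C_j
        return nn.softmax(energy, axis=2)

    def forward(self, a: Tensor) -> Tensor:
        if a.ndim != 4:
            raise ValidationError("position attention expects (N, C, H, W)")
        n, c, h, w = a.shape
        pooled = a
        if h > self.max_grid or w > self.max_grid:
            g = min(self.max_grid, h, w)
            pooled = nn.adaptive_avg_pool2d(a, g)
        pn, pc, ph, pw = pooled.shape
        s = self.attention_map(pooled)                      # (N, P, P)
        d = self.value(pooled).reshape(pn, pc, ph * pw)
        out = (s @ d.transpose(0, 2, 1)).transpose(0, 2, 1).reshape(pn, pc, ph, pw)
        res = nn.upsample_bilinear(out, (h, w))
        return self.alpha.reshape(1, 1, 1, 1) * res + a


class ChannelAttention(nn.Module):
    """Channel self-attention computed from the raw channel vectors
    (no learned projections; only the scale beta is trainable)."""

    def __init__(self, channels: int = 0):
        self.beta = Tensor(np.zeros(1, dtype=np.float32), requires_grad=True)

    def attention_map(self, a: Tensor) -> Tensor:
        """Row-stochastic X of shape (N, C, C)."""
        n, c, h, w = a.shape
        flat = a.reshape(n, c, h * w)
        energy = flat @ flat.transpose(0, 2, 1)             # e[j, i] = A_i . A_j
        return nn.softmax(energy, axis=2)

    def forward(self, a: Tensor) -> Tensor:
        if a.ndim != 4:
            raise ValidationError("channel attention expects (N, C, H, W)")
        n, c, h, w = a.shape
        x = self.attention_map(a)
        flat = a.reshape(n, c, h * w)
        out = (x @ flat).reshape(n, c, h, w)
        return self.beta.reshape(1, 1, 1, 1) * out + a


class MSA(nn.Module):
    """Pyramid pooling followed by parallel position/channel attention.

    The attention branches operate on the 2C-channel fused map; their
    residuals are summed onto it and a final 1x1 convolution restores the
    skip-connection channel count.
    """

    def __init__(self, channels: int, out_channels: int | None = None,
                 grids=_DEFAULT_GRIDS, reduction: int = 4,
                 proj_ratio: int = 8, max_grid: int = 32,
                 *, rng: np.random.Generator):
        out_channels = channels if out_channels is None else out_channels
        self.pool = PyramidPool(channels, grids=grids, reduction=reduction,
                                rng=rng)
        self.pos = PositionAttention(2 * channels, proj_ratio=proj_ratio,
                                     max_grid=max_grid, rng=rng)
        self.chan = ChannelAttention(2 * channels)
        self.project = nn.Conv2d(2 * channels, out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        fused = self.pool(x)
        e = self.pos(fused)
        e_prime = self.chan(fused)
        combined = e + e_prime - fused      # sum of the two attention residuals
        return self.project(combined)
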