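"""Coordinate attention.

Global average pooling is decomposed into two directional pools — one along
width (giving a per-height descriptor ``z_h`` of shape C x H) and one along
height (``z_w``, C x W).  The two descriptors are concatenated along the
spatial axis, compressed to ``C/r`` channels by a shared 1x1 convolution with
batch normalisation and a nonlinearity, split back into height and width
halves, and expanded by two independent 1x1 convolutions whose
sigmoid-activated outputs gate the input map per row and per column:

    y[c, i, j] = x[c, i, j] * g_h[c, i] * g_w[c, j]

Since both gates lie strictly in (0, 1), the block is an element-wise
contraction of its input.

The nonlinearity after the shared transform is hard-swish by default;
``strict_gate_nonlinearity=True`` switches it to a sigmoid, in which case the
per-direction gates apply a second sigmoid on top of an already (0,1)-valued
signal (kept as an option because the narrower gate range is a legitimate,
if unusual, design point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Module, Tensor

__all__ = ["CAMConfig", "DirectionalPools", "pool_directional", "CoordinateAttention",
           "cam_parameter_count"]


@dataclass(frozen=True)
class CAMConfig:
    """Coordinate-attention hyperparameters.

    ``reduction`` is the channel compression ratio r; the compressed width is
    ``max(mid_floor, channels // reduction)``.  ``conv_bias`` and ``norm``
    control whether the 1x1 convs carry biases and whether the shared
    transform is batch-normalised (both on by default, matching the canonical
    design).
    """

    channels: int
    reduction: int = 16
    mid_floor: int = 8
    conv_bias: bool = True
    norm: bool = True
    strict_gate_nonlinearity: bool = False

    def __post_init__(self):
        if self.reduction < 1:
            raise ValueError("reduction must be >= 1")

    @property
    def mid(self) -> int:
        return max(self.mid_floor, self.channels // self.reduction)


@dataclass(frozen=True)
class DirectionalPools:
    """Per-height and per-width mean descriptors of a feature map."""

    z_h: np.ndarray  # (n, c, h)
    z_w: np.ndarray  # (n, c, w)


def pool_directional(x: Tensor | np.ndarray) -> DirectionalPools:
    """Directional average pooling.

    ``z_h[c][i]`` is the mean of row i of channel c; ``z_w[c][j]`` the mean
    of column j.  Averaging ``z_h`` over rows (or ``z_w`` over columns)
    reproduces the global mean exactly.
    """
    data = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float32)
    if data.ndim == 3:
        data = data[None]
    return DirectionalPools(z_h=data.mean(axis=3), z_w=data.mean(axis=2))


class CoordinateAttention(Module):
    def __init__(self, cfg: CAMConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        c, mid = cfg.channels, cfg.mid
        self.conv1 = nn.Conv2d(c, mid, 1, bias=cfg.conv_bias, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid) if cfg.norm else None
        self.conv_h = nn.Conv2d(mid, c, 1, bias=cfg.conv_bias, rng=rng)
        self.conv_w = nn.Conv2d(mid, c, 1, bias=cfg.conv_bias, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        if x.shape[1] != cfg.channels:
            raise ValueError(
                f"coordinate attention expects {cfg.channels} channels, got {x.shape[1]}")
        n, c, h, w = x.shape
        z_h = nn.mean_axis(x, axis=3, keepdims=True)           # (n, c, h, 1)
        z_w = nn.mean_axis(x, axis=2, keepdims=True)           # (n, c, 1, w)
        z_w_t = nn.reshape(z_w, (n, c, w, 1))
        z = nn.concat([z_h, z_w_t], axis=2)                    # (n, c, h+w, 1)
        f = self.conv1(z)
        if self.bn1 is not None:
            f = self.bn1(f)
        f = nn.sigmoid(f) if cfg.strict_gate_nonlinearity else nn.hardswish(f)
        f_h = nn.take(f, (slice(None), slice(None), slice(0, h)))
        f_w = nn.take(f, (slice(None), slice(None), slice(h, h + w)))
        g_h = nn.sigmoid(self.conv_h(f_h))                     # (n, c, h, 1)
        g_w = nn.sigmoid(self.conv_w(nn.reshape(f_w, (n, cfg.mid, 1, w))))
        return nn.mul(nn.mul(x, g_h), g_w)


def cam_parameter_count(channels: int, reduction: int = 16, *, mid_floor: int = 8,
                        conv_bias: bool = True, norm: bool = True) -> int:
    """Closed-form count: shared transform + the two direction gates.

    ``c*mid (+mid) (+2*mid) + 2*(mid*c (+c))`` — approximately ``3*c**2/r``
    for large channel counts.
    """
    mid = max(mid_floor, channels // reduction)
    p = channels * mid
    if conv_bias:
        p += mid
    if norm:
        p += 2 * mid
    p += 2 * (mid * channels + (channels if conv_bias else 0))
    return p
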