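"""Multiscale Attention (MA) block.

A plug-and-play module appended to each backbone branch:

    x --1x1 conv (C -> C/2)--> r --[IC block || IC block]--> concat
      --1x1 conv (back to C/2)--> (+ r, jump connection) --> out

An IC block is an InceptionV1-style multiscale stage (parallel 1x1, 3x3 and
5x5 convolutions plus a pooled branch, channel-concatenated) followed by
CBAM, the sequential channel-then-spatial attention gate.  The jump
connection adds the reduced features back, so zeroing every IC-path
parameter reduces the block to the identity on the reduced features.

Channel counts are configuration, not constants: the default reduces
1024 -> 512 (the backbone's output), and the same block attaches to the
compact test backbone with 64 -> 32.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as np
import numpy as onp

from . import nn

__all__ = ["MAConfig", "CBAM", "ICBlock", "MABlock", "ma_forward", "cbam"]


@dataclass
class MAConfig:
    """Channel plan for one MA block.

    ``reduced_channels`` defaults to half of ``in_channels``;
    ``branch_channels`` (per inception branch) defaults to a quarter of the
    reduced width, so the four branches concatenate back to the reduced
    width.  ``combine_mode`` joins the two parallel IC paths: ``concat``
    (then re-projected by the second 1x1 convolution) or ``add``.
    """

    in_channels: int = 1024
    reduced_channels: int | None = None
    branch_channels: int | None = None
    cbam_reduction: int = 16
    spatial_kernel: int = 7
    combine_mode: str = "concat"

    def __post_init__(self):
        if self.reduced_channels is None:
            self.reduced_channels = self.in_channels // 2
        if self.branch_channels is None:
            self.branch_channels = self.reduced_channels // 4
        if min(self.in_channels, self.reduced_channels,
               self.branch_channels) <= 0:
            raise ValueError("all channel widths must be positive")
        if self.combine_mode not in ("concat", "add"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")


class CBAM(nn.Layer):
    """Convolutional block attention: channel gate then spatial gate.

    The channel gate passes global-average and global-max descriptors
    through a shared two-layer MLP and sigmoids the sum; the spatial gate
    convolves the channel-wise average/max maps with a single k x k kernel.
    Both gates lie in (0, 1) and multiply the input.
    """

    def __init__(self, channels, reduction=16, spatial_kernel=7):
        self.channels = channels
        self.hidden = max(1, channels // reduction)
        self.spatial_kernel = spatial_kernel
        self.mlp1 = nn.Dense(channels, self.hidden)
        self.mlp2 = nn.Dense(self.hidden, channels)
        self.spatial = nn.Conv2D(2, 1, spatial_kernel)

    def init(self, rng):
        return {"mlp1": self.mlp1.init(rng), "mlp2": self.mlp2.init(rng),
                "spatial": self.spatial.init(rng)}

    def channel_gate(self, params, x):
        avg = np.mean(x, axis=(1, 2))
        mx = np.max(x, axis=(1, 2))
        shared = lambda v: self.mlp2(params["mlp2"],
                                     nn.relu(self.mlp1(params["mlp1"], v)))
        return nn.sigmoid(shared(avg) + shared(mx))          # [B, C]

    def spatial_gate(self, params, x):
        avg = np.mean(x, axis=3, keepdims=True)
        mx = np.max(x, axis=3, keepdims=True)
        m = np.concatenate([avg, mx], axis=3)
        return nn.sigmoid(self.spatial(params["spatial"], m))  # [B, H, W, 1]

    def apply(self, params, x):
        x = x * self.channel_gate(params, x)[:, None, None, :]
        return x * self.spatial_gate(params, x)


def cbam(fmap, params=None, reduction=16, spatial_kernel=7, seed=0):
    """Functional CBAM over an NHWC map; random gate weights if none given."""
    layer = CBAM(fmap.shape[3], reduction, spatial_kernel)
    if params is None:
        params = layer.init(onp.random.default_rng(seed))
    return layer(params, fmap)


class ICBlock(nn.Layer):
    """InceptionV1-style multiscale stage followed by CBAM.

    Branches (each ``branch`` channels wide, 'same' padding):
      1x1 conv | 1x1 reduce -> 3x3 conv | 1x1 reduce -> 5x5 conv |
      3x3 max-pool -> 1x1 conv.
    Outputs concatenate to ``channels`` and every convolution is followed by
    batch norm + ReLU.
    """

    def __init__(self, channels, branch=None, cbam_reduction=16,
                 spatial_kernel=7):
        if branch is None:
            branch = channels // 4
        self.channels, self.branch = channels, branch

        def unit(cin, cout, k):
            return nn.Sequential(nn.Conv2D(cin, cout, k),
                                 nn.BatchNorm(cout), nn.ReLU())

        self.b1 = unit(channels, branch, 1)
        self.b3 = nn.Sequential(nn.Conv2D(channels, branch, 1),
                                nn.BatchNorm(branch), nn.ReLU(),
                                nn.Conv2D(branch, branch, 3),
                                nn.BatchNorm(branch), nn.ReLU())
        self.b5 = nn.Sequential(nn.Conv2D(channels, branch, 1),
                                nn.BatchNorm(branch), nn.ReLU(),
                                nn.Conv2D(branch, branch, 5),
                                nn.BatchNorm(branch), nn.ReLU())
        self.bp = nn.Sequential(nn.MaxPool(3, 1, padding="same"),
                                nn.Conv2D(channels, branch, 1),
                                nn.BatchNorm(branch), nn.ReLU())
        self.attn = CBAM(4 * branch, cbam_reduction, spatial_kernel)

    def init(self, rng):
        return {"b1": self.b1.init(rng), "b3": self.b3.init(rng),
                "b5": self.b5.init(rng), "bp": self.bp.init(rng),
                "attn": self.attn.init(rng)}

    def apply(self, params, x):
        y = np.concatenate([self.b1(params["b1"], x),
                            self.b3(params["b3"], x),
                            self.b5(params["b5"], x),
                            self.bp(params["bp"], x)], axis=3)
        return self.attn(params["attn"], y)


class MABlock(nn.Layer):
    def __init__(self, cfg: MAConfig | None = None, **kwargs):
        self.cfg = cfg if cfg is not None else MAConfig(**kwargs)
        c = self.cfg
        self.reduce = nn.Sequential(
            nn.Conv2D(c.in_channels, c.reduced_channels, 1),
            nn.BatchNorm(c.reduced_channels), nn.ReLU())
        self.ic1 = ICBlock(c.reduced_channels, c.branch_channels,
                           c.cbam_reduction, c.spatial_kernel)
        self.ic2 = ICBlock(c.reduced_channels, c.branch_channels,
                           c.cbam_reduction, c.spatial_kernel)
        cin = (8 * c.branch_channels if c.combine_mode == "concat"
               else 4 * c.branch_channels)
        self.combine = nn.Conv2D(cin, c.reduced_channels, 1)

    @property
    def out_channels(self):
        return self.cfg.reduced_channels

    def init(self, rng):
        return {"reduce": self.reduce.init(rng),
                "ic1": self.ic1.init(rng), "ic2": self.ic2.init(rng),
                "combine": self.combine.init(rng)}

    def reduced(self, params, x):
        return self.reduce(params["reduce"], x)

    def apply(self, params, x):
        if x.shape[3] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, "
                             f"got {x.shape[3]}")
        r = self.reduce(params["reduce"], x)
        y1 = self.ic1(params["ic1"], r)
        y2 = self.ic2(params["ic2"], r)
        if self.cfg.combine_mode == "concat":
            y = np.concatenate([y1, y2], axis=3)
        else:
            y = y1 + y2
        return self.combine(params["combine"], y) + r


def ma_forward(fmap, cfg=None, params=None, seed=0):
    """One-shot MA forward; builds (and randomly initialises) a block when no
    parameters are supplied."""
    if cfg is None:
        cfg = MAConfig(in_channels=int(fmap.shape[3]))
    block = MABlock(cfg)
    if params is None:
        params = block.init(onp.random.default_rng(seed))
    return block(params, fmap)
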