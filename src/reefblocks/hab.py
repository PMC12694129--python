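"""Holistic attention detection head.

Three pieces, bottom-up:

* LGA (local-global attention): tokenizes the feature map into p x p
  patches, reduces each patch across channels by mean pooling, encodes it
  with a two-layer MLP, self-gates it, and gates it again by its clamped
  cosine relevance to a learnable global prompt vector.  The refined patch
  sequence is reassembled to the patch grid, bilinearly upsampled to the
  input resolution and mixed by a 1x1 convolution.

* HAB (holistic attention block): additive dense fusion of six pathways —
  a 1x1 skip, a three-deep 3x3 convolutional chain (each intermediate also
  fused), and two LGA units at patch sizes 2 and 4 applied to the skip map —
  refined by efficient channel attention (ECA) and spatial attention (SAM),
  then batch-norm and ReLU.

* HABHead: per pyramid level (strides 8/16/32), two stacked HABs followed by
  lightweight 1x1 classification and box-regression convolutions.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ConfigurationError
from .nn import (BatchNorm2d, Conv2d, ConvBlock, Linear, Module, Parameter,
                 Tensor, functional as F)

__all__ = ["LGAConfig", "LGA", "lga_relevance_mask", "HAB", "HABHead", "ECA", "SAM"]


@dataclasses.dataclass(frozen=True)
class LGAConfig:
    patch_size: int = 2
    channels: int = 64
    epsilon: float = 1e-6

    def validate(self):
        if self.patch_size < 1:
            raise ConfigurationError("patch_size must be >= 1")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")


def lga_relevance_mask(l_prime: Tensor, pg: Tensor, eps: float) -> Tensor:
    """Clamped cosine relevance of each patch feature to the global prompt.

    l_prime: (..., C); pg: (C,).  Returns values in [0, 1]; the epsilon in
    the denominator makes zero vectors safe.
    """
    dot = (l_prime * pg).sum(axis=-1)
    norm_l = F.sqrt((l_prime * l_prime).sum(axis=-1))
    norm_p = F.sqrt((pg * pg).sum(axis=-1))
    return F.clamp(dot / (norm_l * norm_p + eps), 0.0, 1.0)


class LGA(Module):
    def __init__(self, cfg: LGAConfig, *, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        p, c = cfg.patch_size, cfg.channels
        # two-layer MLP: p*p patch vector -> C
        self.enc1 = Linear(p * p, c, rng=rng)
        self.enc2 = Linear(c, c, rng=rng)
        # global prompt: unit-normal scaled by 1/sqrt(C) keeps initial cosines small
        self.prompt = Parameter(rng.normal(0, 1, size=c) / np.sqrt(c))
        self.w_td = Parameter(rng.normal(0, 1 / np.sqrt(c), size=(c, c)))
        self.proj = Conv2d(c, c, k=1, rng=rng)

    def encode_patches(self, x: Tensor) -> Tensor:
        """Channel-mean patch vectors through the MLP: (B, N_patches, C),
        row-major patch order.  Spatial dims must already be multiples of p."""
        p = self.cfg.patch_size
        b, c, h, w = x.shape
        xm = x.mean(axis=1)  # (B, H, W) channel mean
        gh, gw = h // p, w // p
        patches = (xm.reshape(b, gh, p, gw, p)
                   .transpose(0, 1, 3, 2, 4)
                   .reshape(b, gh * gw, p * p))
        return self.enc2(F.relu(self.enc1(patches)))

    def _pad(self, x: Tensor) -> Tensor:
        p = self.cfg.patch_size
        b, c, h, w = x.shape
        dh, dw = (-h) % p, (-w) % p
        if dh:
            x = F.concatenate(
                [x, Tensor(np.zeros((b, c, dh, w), dtype=np.float32))], axis=2)
        if dw:
            x = F.concatenate(
                [x, Tensor(np.zeros((b, c, h + dh, dw), dtype=np.float32))], axis=3)
        return x

    def forward(self, x: Tensor, return_premap: bool = False):
        p, eps = self.cfg.patch_size, self.cfg.epsilon
        b, c, h, w = x.shape
        xp = self._pad(x)
        hp, wp = xp.shape[2], xp.shape[3]
        gh, gw = hp // p, wp // p
        l = self.encode_patches(xp)                       # (B, N, C)
        l_prime = l * F.softmax(l, axis=-1)               # self-gating
        m = lga_relevance_mask(l_prime, self.prompt, eps)  # (B, N)
        refined = (l_prime * m.reshape(b, gh * gw, 1)) @ self.w_td
        grid = refined.reshape(b, gh, gw, c).transpose(0, 3, 1, 2)
        up = F.upsample_bilinear2d(grid, hp, wp)[:, :, :h, :w]
        if return_premap:
            return up
        return self.proj(up)


class ECA(Module):
    """Efficient channel attention: GAP descriptor, 1-D conv (k=3) across
    channels, sigmoid gate."""

    def __init__(self, channels: int, k: int = 3, *, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(1, 1, k=1, kw=k, padding=(0, k // 2), bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        desc = x.mean(axis=(2, 3)).reshape(b, 1, 1, c)
        gate = F.sigmoid(self.conv(desc)).reshape(b, c, 1, 1)
        return x * gate


class SAM(Module):
    """Spatial attention: channel mean+max maps, 7x7 conv, sigmoid gate."""

    def __init__(self, k: int = 7, *, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(2, 1, k=k, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        gate = F.sigmoid(self.conv(F.concatenate([avg, mx], axis=1)))
        return x * gate


@dataclasses.dataclass(frozen=True)
class HABConfig:
    in_channels: int
    out_channels: int
    lga_patch_sizes: tuple[int, ...] = (2, 4)

    def validate(self):
        if self.in_channels <= 0 or self.out_channels <= 0:
            raise ConfigurationError("channel counts must be positive")


class HAB(Module):
    """One holistic attention block (six-way additive fusion + refinement)."""

    def __init__(self, cin: int, cout: int,
                 lga_patch_sizes: tuple[int, ...] = (2, 4), *,
                 rng: np.random.Generator):
        super().__init__()
        HABConfig(cin, cout, lga_patch_sizes).validate()
        self.c_skip = ConvBlock(cin, cout, k=1, rng=rng)
        self.c1 = ConvBlock(cin, cout, k=3, rng=rng)
        self.c2 = ConvBlock(cout, cout, k=3, rng=rng)
        self.c3 = ConvBlock(cout, cout, k=3, rng=rng)
        self.lgas = [LGA(LGAConfig(patch_size=p, channels=cout), rng=rng)
                     for p in lga_patch_sizes]
        self.eca = ECA(cout, rng=rng)
        self.sam = SAM(rng=rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        x_skip = self.c_skip(x)
        x1 = self.c1(x)
        x2 = self.c2(x1)
        x_deep = self.c3(x2)
        x_agg = x_skip + x1 + x2 + x_deep
        for lga in self.lgas:
            x_agg = x_agg + lga(x_skip)
        return F.relu(self.bn(self.sam(self.eca(x_agg))))


class HABHead(Module):
    """Stacked-HAB detection head over a 3-level pyramid (strides 8/16/32).

    Each level runs two consecutive HABs, then 1x1 convolutions emit class
    logits (n_classes channels) and box regression (4 channels)."""

    def __init__(self, level_channels: tuple[int, int, int], n_classes: int,
                 stacks: int = 2, lga_patch_sizes: tuple[int, ...] = (2, 4), *,
                 rng: np.random.Generator):
        super().__init__()
        if len(level_channels) != 3:
            raise ConfigurationError("HABHead expects exactly 3 pyramid levels")
        self.n_classes = n_classes
        self.stacks_per_level = []
        self.cls_convs = []
        self.reg_convs = []
        for c in level_channels:
            blocks = [HAB(c, c, lga_patch_sizes, rng=rng) for _ in range(stacks)]
            self.stacks_per_level.append(blocks)
            cls_conv = Conv2d(c, n_classes, k=1, rng=rng)
            cls_conv.bias.data[:] = -np.log(99.0)  # focal prior: p0 ~ 0.01
            reg_conv = Conv2d(c, 4, k=1, rng=rng)
            reg_conv.bias.data[:] = 0.0  # offsets centered, size ~ 1 stride
            self.cls_convs.append(cls_conv)
            self.reg_convs.append(reg_conv)
        # register nested lists for parameter discovery
        for i, blocks in enumerate(self.stacks_per_level):
            for j, blk in enumerate(blocks):
                self._modules[f"hab{i}.{j}"] = blk
        for i, (cc, rc) in enumerate(zip(self.cls_convs, self.reg_convs)):
            self._modules[f"cls{i}"] = cc
            self._modules[f"reg{i}"] = rc

    def forward(self, levels) -> list[tuple[Tensor, Tensor]]:
        if len(levels) != 3:
            raise ConfigurationError("HABHead expects exactly 3 pyramid levels")
        out = []
        for i, x in enumerate(levels):
            for blk in self.stacks_per_level[i]:
                x = blk(x)
            out.append((self.cls_convs[i](x), self.reg_convs[i](x)))
        return out
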