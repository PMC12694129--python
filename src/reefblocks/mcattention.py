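"""Monte Carlo channel attention.

A squeeze-excite style channel attention whose context vector is randomized
during training and deterministic at inference:

* train: a fresh random spatial permutation of the feature map, adaptive
  average pooling to a resolution p drawn uniformly from a pooling set
  (default {1, 2, 3}), and — for p > 1 — a single uniformly chosen cell of
  the pooled map;
* eval: plain global average pooling, consuming no randomness at all.

Both phases feed the same two-layer 1x1 mapping network; the sigmoid output
recalibrates channels multiplicatively.  Randomizing the context during
training regularizes the attention toward layout- and scale-invariant
channel relationships.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ConfigurationError
from .nn import Conv2d, Module, Tensor, functional as F
from .nn.tensor import as_tensor

__all__ = ["MCAttentionConfig", "MCAttention", "stochastic_context",
           "deterministic_context"]


@dataclasses.dataclass(frozen=True)
class MCAttentionConfig:
    pooling_set: tuple[int, ...] = (1, 2, 3)
    reduction: int = 16

    def validate(self):
        if not self.pooling_set or min(self.pooling_set) < 1:
            raise ConfigurationError("pooling_set must be nonempty with min >= 1")
        if self.reduction < 1:
            raise ConfigurationError("reduction must be >= 1")


def _permute_spatial(x: Tensor, perms: np.ndarray) -> Tensor:
    """Apply a per-sample permutation of flattened (H*W) positions, shared
    across channels.  Gradient is the inverse permutation (a bijection, so
    no scatter-add is needed)."""
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    flat = x.data.reshape(b, c, h * w)
    out_data = np.take_along_axis(flat, perms[:, None, :], axis=2).reshape(b, c, h, w)
    inv = np.argsort(perms, axis=1)

    def bwd(g):
        if x.requires_grad:
            gf = g.reshape(b, c, h * w)
            x._accum(np.take_along_axis(gf, inv[:, None, :], axis=2).reshape(x.data.shape))

    return Tensor._make(out_data, (x,), bwd)


def _adaptive_avg_cells(x: Tensor, p: int) -> list[Tensor]:
    """Adaptive p x p average pooling, returned as p*p per-cell (B, C)
    tensors in row-major order (bin edges floor(i*H/p), as usual)."""
    h, w = x.shape[2], x.shape[3]
    hs = [int(np.floor(i * h / p)) for i in range(p + 1)]
    ws = [int(np.floor(j * w / p)) for j in range(p + 1)]
    cells = []
    for i in range(p):
        for j in range(p):
            cells.append(
                x[:, :, hs[i]:hs[i + 1], ws[j]:ws[j + 1]].mean(axis=(2, 3)))
    return cells


def stochastic_context(x: Tensor, cfg: MCAttentionConfig,
                       rng: np.random.Generator) -> Tensor:
    """Training-phase context: permute, pool to a random resolution, sample.

    Returns a (B, C) tensor.  A fresh permutation (per sample) and pooling
    resolution (per forward call) are drawn from ``rng`` on every call.
    """
    cfg.validate()
    b, c, h, w = x.shape
    perms = np.stack([rng.permutation(h * w) for _ in range(b)])
    xp = _permute_spatial(x, perms)
    p = int(rng.choice(np.asarray(cfg.pooling_set)))
    if p == 1:
        return xp.mean(axis=(2, 3))
    cells = _adaptive_avg_cells(xp, p)  # p*p tensors (B, C)
    stacked = F.concatenate([ci.reshape(b, 1, c) for ci in cells], axis=1)
    choice = rng.integers(0, p * p, size=b)
    return stacked[np.arange(b), choice]  # (B, C)


def deterministic_context(x: Tensor) -> Tensor:
    """Inference-phase context: the exact spatial mean per channel, (B, C)."""
    return x.mean(axis=(2, 3))


class MCAttention(Module):
    def __init__(self, channels: int, cfg: MCAttentionConfig | None = None, *,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg or MCAttentionConfig()
        self.cfg.validate()
        hidden = max(channels // self.cfg.reduction, 1)
        self.fc1 = Conv2d(channels, hidden, k=1, rng=rng)
        self.fc2 = Conv2d(hidden, channels, k=1, rng=rng)

    def attention_weights(self, ctx: Tensor) -> Tensor:
        b, c = ctx.shape
        z = ctx.reshape(b, c, 1, 1)
        return F.sigmoid(self.fc2(F.relu(self.fc1(z))))

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if self.training:
            if rng is None:
                raise ConfigurationError("training-mode MCAttention requires an rng")
            ctx = stochastic_context(x, self.cfg, rng)
        else:
            ctx = deterministic_context(x)
        return x * self.attention_weights(ctx)
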