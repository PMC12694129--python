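"""AdamW optimizer and the cosine learning-rate schedule used for training."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["AdamW", "cosine_lr"]


class AdamW:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.937, 0.999), eps: float = 1e-8,
                 weight_decay: float = 5e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data  # decoupled decay
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cosine_lr(epoch: int, total_epochs: int, lr0: float, lrf: float = 0.01,
              warmup_epochs: float = 0.0) -> float:
    """Cosine annealing from lr0 to lr0*lrf, with optional linear warm-up."""
    if warmup_epochs > 0 and epoch < warmup_epochs:
        return lr0 * (epoch + 1) / warmup_epochs
    span = max(total_epochs - warmup_epochs, 1)
    t = (epoch - warmup_epochs) / span
    return lr0 * (lrf + (1 - lrf) * 0.5 * (1 + np.cos(np.pi * t)))
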