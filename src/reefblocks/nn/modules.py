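"""Layer and container abstractions over the autograd tensors."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "Sequential",
           "ReLU", "SiLU", "ConvBlock"]


class Module:
    """Base class: parameter registration by attribute, train/eval mode."""

    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Parameter] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        seen, out = set(), []
        for p in self._params.values():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        for m in self._modules.values():
            for p in m.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mn + "."))
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def modules(self):
        """All submodules, depth-first, including self."""
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def freeze_bn_stats(self, freeze: bool = True):
        for m in self._modules.values():
            m.freeze_bn_stats(freeze)
        if hasattr(self, "freeze_stats"):
            self.freeze_stats = freeze
        return self

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + n: p.data.copy() for n, p in self._params.items()}
        for mn, m in self._modules.items():
            out.update(m.state_dict(prefix + mn + "."))
        for n, buf in getattr(self, "_buffers", {}).items():
            out[prefix + n] = buf.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for n, p in self._params.items():
            p.data = np.asarray(state[prefix + n], dtype=np.float32).copy()
        for n in getattr(self, "_buffers", {}):
            self._buffers[n] = np.asarray(state[prefix + n], dtype=np.float32).copy()
        for mn, m in self._modules.items():
            m.load_state_dict(state, prefix + mn + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 padding=None, bias: bool = True, *, rng: np.random.Generator,
                 kw: int | None = None):
        super().__init__()
        kh = k
        kw = k if kw is None else kw
        if padding is None:
            padding = (kh // 2, kw // 2)
        self.stride, self.padding = stride, padding
        self.weight = Parameter(kaiming(rng, (cout, cin, kh, kw), cin * kh * kw))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Batch normalization with freezable statistics.

    ``freeze_stats`` pins the running statistics and uses them in both
    training and eval forward passes (gamma/beta keep training) — the usual
    remedy for the train/eval normalization gap in small-batch regimes."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.freeze_stats = False
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self._buffers = {
            "running_mean": np.zeros(c, dtype=np.float32),
            "running_var": np.ones(c, dtype=np.float32),
        }

    def forward(self, x: Tensor) -> Tensor:
        if self.training and not self.freeze_stats:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu)
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var)
            return F.batch_norm2d(x, self.gamma, self.beta, mu, var, self.eps)
        return F.batch_norm2d_eval(x, self.gamma, self.beta,
                                   self._buffers["running_mean"],
                                   self._buffers["running_var"], self.eps)


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(kaiming(rng, (cin, cout), cin))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class SiLU(Module):
    def forward(self, x):
        return F.silu(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ConvBlock(Module):
    """Convolution + batch norm + SiLU (the YOLO-family 'Conv' block)."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, *,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = SiLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))
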