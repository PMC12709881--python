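"""Neural-network building blocks over the autograd engine.

Initialisation is He-style for convolutions and linear layers, driven
by a ``numpy.random.Generator`` so that a model built twice from the
same seed has bit-identical parameters.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from .autograd import Tensor, conv2d


class Module:
    """Minimal module base: parameter registry and train/eval mode."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Tensor]:
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, v in self._params.items():
            yield f"{prefix}{k}", v
        for name, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{name}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_buffers():
            state[name] = m.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32)
        for name, _ in self._named_buffers():
            owner, attr = self._resolve_buffer(name)
            setattr(owner, attr, np.asarray(state[name], dtype=np.float32))

    # buffers: running batch-norm statistics
    def _named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for attr in getattr(self, "_buffers", ()):  # type: ignore[attr-defined]
            yield f"{prefix}{attr}", getattr(self, attr)
        for name, m in self._modules.items():
            yield from m._named_buffers(f"{prefix}{name}.")

    def _resolve_buffer(self, dotted: str) -> tuple["Module", str]:
        parts = dotted.split(".")
        owner: Module = self
        for p in parts[:-1]:
            owner = owner._modules[p]
        return owner, parts[-1]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """Stride-1 'same'-padded convolution with odd square kernels."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(
            _he_init(rng, (out_ch, in_ch, kernel, kernel), in_ch * kernel * kernel),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Tensor(_he_init(rng, (in_f, out_f), in_f), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Per-channel normalisation over (N, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(c))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(c))
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ConvBNReLU(Module):
    """conv3×3 → batch norm → ReLU, the U-Net workhorse."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class RMSprop:
    """RMSprop with framework-default internals (alpha 0.99, eps 1e-8, no momentum)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.sq_avg = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, sq in zip(self.params, self.sq_avg):
            if p.grad is None:
                continue
            sq *= self.alpha
            sq += (1 - self.alpha) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(sq) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class ReduceLROnPlateau:
    """Halve the learning rate when a monitored score stops improving.

    Monitors a quantity where larger is better (validation Dice);
    ``factor`` 0.5, ``patience`` 5, floored at ``lr_min``.
    """

    def __init__(self, optimizer: RMSprop, lr_min: float = 1e-5,
                 factor: float = 0.5, patience: int = 5):
        self.optimizer = optimizer
        self.lr_min = lr_min
        self.factor = factor
        self.patience = patience
        self.best = -np.inf
        self.stale = 0

    def step(self, score: float) -> None:
        if score > self.best + 1e-12:
            self.best = score
            self.stale = 0
        else:
            self.stale += 1
            if self.stale > self.patience:
                self.optimizer.lr = max(self.lr_min, self.optimizer.lr * self.factor)
                self.stale = 0


class CosineSchedule:
    """Cosine decay from the initial rate to ``lr_min`` over ``total`` steps."""

    def __init__(self, optimizer: RMSprop, lr_min: float, total: int):
        self.optimizer = optimizer
        self.lr_init = optimizer.lr
        self.lr_min = lr_min
        self.total = max(1, total)
        self.t = 0

    def step(self, score: float | None = None) -> None:
        self.t = min(self.t + 1, self.total)
        cos = 0.5 * (1 + np.cos(np.pi * self.t / self.total))
        self.optimizer.lr = self.lr_min + (self.lr_init - self.lr_min) * cos
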