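"""Module system and layers built on the autograd engine.

Mirrors the familiar Module/Sequential idiom: attribute assignment
registers parameters and child modules, `state_dict` round-trips weights
and batch-norm running statistics as plain numpy arrays.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import (
    Parameter,
    Tensor,
    conv2d,
    global_avg_pool,
    maxpool2d,
    relu,
    sigmoid,
    silu,
)

__all__ = [
    "Module",
    "Sequential",
    "ModuleList",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "ReLU",
    "SiLU",
    "Sigmoid",
    "MaxPool2d",
    "GlobalAvgPool",
    "Dropout",
    "Identity",
    "seed_dropout",
]

# Shared RNG for dropout masks; trainers re-seed it for reproducible runs.
_DROPOUT_RNG = np.random.default_rng(0)


def seed_dropout(seed: int) -> None:
    global _DROPOUT_RNG
    _DROPOUT_RNG = np.random.default_rng(seed)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization ------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        sd = {name: p.data.copy() for name, p in self.named_parameters()}
        sd.update({name: b.copy() for name, b in self.named_buffers()})
        return sd

    def load_state_dict(self, sd: dict[str, np.ndarray]) -> None:
        own_params = dict(self.named_parameters())
        own_bufs = dict(self.named_buffers())
        missing = (set(own_params) | set(own_bufs)) - set(sd)
        unexpected = set(sd) - (set(own_params) | set(own_bufs))
        if missing or unexpected:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} unexpected={sorted(unexpected)}"
            )
        for name, p in own_params.items():
            arr = np.asarray(sd[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        # buffers live on their owning module; walk children to reassign
        self._load_buffers(sd, prefix="")

    def _load_buffers(self, sd, prefix):
        for name in list(self._buffers):
            full = prefix + name
            arr = np.asarray(sd[full], dtype=np.float64)
            if arr.shape != self._buffers[name].shape:
                raise ValueError(f"shape mismatch for buffer {full}")
            self._set_buffer(name, arr.copy())
        for name, m in self._modules.items():
            m._load_buffers(sd, prefix + name + ".")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, x):
        return self.forward(x)

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._order = [str(i) for i in range(len(mods))]

    def __iter__(self):
        return iter(self._modules[k] for k in self._order)

    def forward(self, x):
        for k in self._order:
            x = self._modules[k](x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._order = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        key = str(len(self._order))
        setattr(self, key, m)
        self._order.append(key)

    def __len__(self):
        return len(self._order)

    def __iter__(self):
        return iter(self._modules[k] for k in self._order)

    def __getitem__(self, i):
        return self._modules[self._order[i]]


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride=1, padding=0, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        if in_channels % groups:
            raise ValueError("in_channels must be divisible by groups")
        fan_in = (in_channels // groups) * kh * kw
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels // groups, kh, kw)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Per-channel normalization; batch statistics in train mode, running
    (exponential-average, biased) statistics in eval mode."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones((1, num_features, 1, 1)))
        self.beta = Parameter(np.zeros((1, num_features, 1, 1)))
        self.eps, self.momentum = eps, momentum
        self.register_buffer("running_mean", np.zeros((1, num_features, 1, 1)))
        self.register_buffer("running_var", np.ones((1, num_features, 1, 1)))

    def forward(self, x):
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - m
            v = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self._set_buffer(
                "running_mean",
                (1 - self.momentum) * self.running_mean + self.momentum * m.data,
            )
            self._set_buffer(
                "running_var",
                (1 - self.momentum) * self.running_var + self.momentum * v.data,
            )
            inv = (v + self.eps) ** -0.5
            return xc * inv * self.gamma + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - self.running_mean) * inv * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class SiLU(Module):
    def forward(self, x):
        return silu(x)


class Sigmoid(Module):
    def forward(self, x):
        return sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return maxpool2d(x, self.kernel_size, self.stride, self.padding)


class GlobalAvgPool(Module):
    def forward(self, x):
        return global_avg_pool(x)


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return x
        mask = (_DROPOUT_RNG.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Identity(Module):
    def forward(self, x):
        return x
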