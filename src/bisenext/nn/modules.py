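"""Layer/container abstractions over the autograd primitives."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autograd as A
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter registry, train/eval mode, state dict."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for n, b in self._buffers.items():
            yield prefix + n, b
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix + mn + ".")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {n: p.data.copy() for n, p in self.named_parameters()}
        out.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                buf[...] = value
            else:
                p = params[key]
                if p.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: {p.shape} vs {value.shape}")
                p.data[...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._seq = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._seq)


class ReLU(Module):
    def forward(self, x):
        return A.relu(x)


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride: int = 1, padding=0, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = (kh, kw)
        self.stride = stride
        self.padding = padding
        self.groups = groups
        rng = rng or np.random.default_rng()
        fan_in = (in_channels // groups) * kh * kw
        std = math.sqrt(2.0 / fan_in)   # He initialisation for ReLU nets
        w = rng.normal(0.0, std, (out_channels, in_channels // groups, kh, kw))
        self.weight = Parameter(w.astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        return A.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = math.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0, std, (out_features, in_features)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x):
        return A.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x):
        return A.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class GroupNorm(Module):
    """Group normalisation, composed from differentiable primitives."""

    def __init__(self, num_groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % num_groups:
            raise ValueError("channels must divide into groups")
        self.num_groups = num_groups
        self.channels = channels
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x):
        B, C, H, W = x.shape
        g = self.num_groups
        xg = A.reshape(x, (B, g, C // g * H * W))
        mu = A.reduce_mean(xg, axis=2, keepdims=True)
        cen = xg - mu
        var = A.reduce_mean(cen * cen, axis=2, keepdims=True)
        xhat = cen * A.power(var + self.eps, -0.5)
        xhat = A.reshape(xhat, (B, C, H, W))
        wshape = (1, C, 1, 1)
        return xhat * A.reshape(self.weight, wshape) + A.reshape(self.bias, wshape)


class ConvBNReLU(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 groups: int = 1, act: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride=stride, padding=k // 2,
                           groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        return A.relu(x) if self.act else x


class SGD:
    """SGD with momentum and decoupled-from-nothing classic weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
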