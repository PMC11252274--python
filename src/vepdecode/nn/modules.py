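"""Layer/module system on top of the autodiff core.

Mirrors the familiar ``Module`` idiom: parameters are discovered by attribute
walking, ``train()``/``eval()`` toggle stochastic layers, and ``state_dict``
round-trips plain numpy arrays so checkpoints stay framework-free.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import core
from .core import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)
        self.requires_grad = True  # parameters ignore no_grad at creation


class Module:
    def __init__(self):
        self.training = True

    # -- registry -------------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_modules(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{prefix}{name}.{i}.")

    def named_buffers(self, prefix: str = ""):
        for mod_name, mod in self.named_modules():
            for bname in getattr(mod, "_buffers", ()):
                key = f"{mod_name}.{bname}" if mod_name else bname
                yield key, getattr(mod, bname)

    # -- modes ----------------------------------------------------------------
    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def seed_rng(self, seed: int):
        """Give every stochastic layer (dropout) a deterministic generator."""
        rng = np.random.default_rng(seed)
        for _, m in self.named_modules():
            if isinstance(m, Dropout):
                m.rng = np.random.default_rng(rng.integers(2 ** 31))
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def parameter_inventory(self) -> dict[str, int]:
        return {name: int(p.data.size) for name, p in self.named_parameters()}

    # -- serialization --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = np.array(buf, copy=True)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.shape)
        for mod_name, mod in self.named_modules():
            for bname in getattr(mod, "_buffers", ()):
                key = f"{mod_name}.{bname}" if mod_name else bname
                getattr(mod, bname)[...] = state[key]
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv2d(Module):
    """Grouped 2-D convolution with optional 'same' (possibly asymmetric) padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel, rng, *,
                 stride=1, padding="valid", groups: int = 1, bias: bool = True):
        super().__init__()
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        self.stride = stride
        self.groups = groups
        if padding == "same":
            self.padding = ((kh - 1) // 2, kh // 2, (kw - 1) // 2, kw // 2)
        elif padding == "valid":
            self.padding = (0, 0, 0, 0)
        else:
            self.padding = tuple(padding)
        fan_in = in_ch // groups * kh * kw
        fan_out = out_ch // groups * kh * kw
        self.weight = Parameter(_glorot(rng, (out_ch, in_ch // groups, kh, kw),
                                        fan_in, fan_out))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return core.conv2d(x, self.weight, self.bias, stride=self.stride,
                           padding=self.padding, groups=self.groups)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng, *, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_glorot(rng, (in_f, out_f), in_f, out_f))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = core.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    _buffers = ("running_mean", "running_var")

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(n_ch))
        self.bias = Parameter(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch, dtype=np.float64)
        self.running_var = np.ones(n_ch, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return core.batch_norm(x, self.weight, self.bias, self.running_mean,
                               self.running_var, self.training,
                               self.momentum, self.eps)


class GroupNorm(Module):
    def __init__(self, groups: int, n_ch: int, eps: float = 1e-5):
        super().__init__()
        self.groups = groups
        self.eps = eps
        self.weight = Parameter(np.ones(n_ch))
        self.bias = Parameter(np.zeros(n_ch))

    def forward(self, x: Tensor) -> Tensor:
        return core.group_norm(x, self.weight, self.bias, self.groups, self.eps)


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        return core.dropout(x, self.p, self.rng, self.training)


class ELU(Module):
    def forward(self, x):
        return x.elu()


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class MaxPool2d(Module):
    def __init__(self, kernel):
        super().__init__()
        self.kernel = kernel

    def forward(self, x):
        return core.max_pool2d(x, self.kernel)


class AvgPool2d(Module):
    def __init__(self, kernel):
        super().__init__()
        self.kernel = kernel

    def forward(self, x):
        return core.avg_pool2d(x, self.kernel)


class Flatten(Module):
    def forward(self, x):
        return x.reshape(x.shape[0], -1)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def __getitem__(self, i):
        return self.layers[i]
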