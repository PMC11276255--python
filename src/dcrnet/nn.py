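"""Layer/module abstractions over :mod:`dcrnet.autograd`.

A deliberately small subset of the usual neural-network module protocol:
modules own :class:`~dcrnet.autograd.Parameter` leaves and non-trainable
buffers (batch-norm running statistics), support recursive parameter
iteration, a train/eval flag, and flat ``state_dict`` round-trips for
checkpointing.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor


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

    # -- traversal ------------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield f"{prefix}{k}", p
        for k, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{k}.")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k in self._buffers:
            yield f"{prefix}{k}", self._buffers[k]
        for k, m in self._modules.items():
            yield from m.named_buffers(f"{prefix}{k}.")

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

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

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- serialisation --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            out[f"{name}"] = b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = []
        for name, p in params.items():
            if name not in state:
                missing.append(name)
                continue
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{state[name].shape} vs {p.data.shape}")
            p.data = np.array(state[name], dtype=p.data.dtype)
        # buffers are updated in place so modules keep their aliases
        for m, prefix in _walk(self):
            for k, b in m._buffers.items():
                key = f"{prefix}{k}"
                if key in state:
                    b[...] = state[key]
        if missing:
            raise ValueError(f"state dict missing parameters: {missing[:5]}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _walk(module: Module, prefix: str = ""):
    yield module, prefix
    for k, m in module._modules.items():
        yield from _walk(m, f"{prefix}{k}.")


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Conv2d(Module):
    """Grouped 2-D convolution with He-normal weight initialisation."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = False, zero_init: bool = False, dtype=np.float32):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError(f"channels ({in_ch}->{out_ch}) not divisible by groups={groups}")
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_ch // groups) * kernel * kernel
        if zero_init:
            w = np.zeros((out_ch, in_ch // groups, kernel, kernel), dtype=dtype)
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           (out_ch, in_ch // groups, kernel, kernel)).astype(dtype)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(ch, dtype=dtype))
        self.beta = Parameter(np.zeros(ch, dtype=dtype))
        self.register_buffer("running_mean", np.zeros(ch, dtype=np.float64))
        self.register_buffer("running_var", np.ones(ch, dtype=np.float64))

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                               self.running_var, self.training,
                               momentum=self.momentum, eps=self.eps)


class DeformableConv2d(Module):
    """Deformable convolution: a learned side branch predicts per-location,
    per-tap fractional sampling offsets ΔPn; the main kernel then samples the
    input at the displaced positions with bilinear interpolation.

    The offset branch is zero-initialised so the layer starts out exactly
    equal to a standard convolution and the offsets are free to be trained
    away from zero.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, groups: int = 1, bias: bool = False):
        super().__init__()
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_ch, in_ch // groups, kernel, kernel)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self.offset_conv = Conv2d(in_ch, 2 * kernel * kernel, kernel, rng,
                                  stride=stride, padding=padding, bias=True, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        offsets = self.offset_conv(x)
        return ag.deform_conv2d(x, self.weight, offsets, self.bias,
                                stride=self.stride, padding=self.padding,
                                groups=self.groups)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 std: float | None = None, dtype=np.float32):
        super().__init__()
        if std is None:
            std = np.sqrt(2.0 / in_f)
        self.weight = Parameter(rng.normal(0.0, std, (out_f, in_f)).astype(dtype))
        self.bias = Parameter(np.zeros(out_f, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)
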