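"""Network building blocks on top of the autograd engine.

Weight initialisation follows the common translation-network convention:
convolution weights ~ N(0, 0.02), biases zero.  Instance normalisation is
used without learnable affine parameters.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter collection and gradient reset."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, pad_mode: str = "zeros", bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.pad = pad
        self.pad_mode = pad_mode
        self.weight = Tensor(
            rng.normal(0.0, 0.02, size=(out_ch, in_ch, kernel, kernel)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if self.pad_mode == "reflect" and self.pad:
            x = ag.reflect_pad2d(x, self.pad)
            return ag.conv2d(x, self.weight, self.bias, self.stride, 0)
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class InstanceNorm(Module):
    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.instance_norm(x, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return ag.leaky_relu(x, self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.tanh(x)


class UpsampleNearest2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.upsample_nearest2(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


class ResidualBlock(Module):
    """Two reflect-padded 3x3 convolutions with a skip connection."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.body = Sequential(
            Conv2d(channels, channels, 3, pad=1, pad_mode="reflect", rng=rng),
            InstanceNorm(),
            ReLU(),
            Conv2d(channels, channels, 3, pad=1, pad_mode="reflect", rng=rng),
            InstanceNorm(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return ag.add(x, self.body(x))
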