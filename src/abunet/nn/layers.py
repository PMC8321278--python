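"""Layer classes over the autodiff ops, with explicit forward contexts.

A :class:`ForwardContext` states, per forward pass, whether the network is in
gradient-training mode, whether dropout masks are sampled (stochastic
inference), and whether batch-norm uses fresh batch statistics instead of its
frozen running averages (optional Monte-Carlo batch norm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor


@dataclass
class ForwardContext:
    training: bool = False        # gradients + batch statistics + dropout
    stochastic: bool = False      # dropout active without gradients (MC pass)
    mc_batchnorm: bool = False    # re-estimate BN statistics from the batch
    rng: np.random.Generator | None = None

    @property
    def dropout_active(self) -> bool:
        return self.training or self.stochastic


class Module:
    def parameters(self) -> list[Tensor]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def forward(self, x: Tensor, ctx: ForwardContext) -> Tensor:
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(cout, cin, k, k)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.k = k
        self.pad = (k - 1) // 2

    def forward(self, x, ctx):
        return ag.conv2d(x, self.weight, self.bias, self.pad)


class ConvTranspose2d(Module):
    """2x2 stride-2 up-convolution."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * 4))
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(cin, cout, 2, 2)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x, ctx):
        return ag.conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum

    def forward(self, x, ctx):
        use_batch_stats = ctx.training or ctx.mc_batchnorm
        if use_batch_stats:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            if ctx.training:
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mean
                self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        return ag.batchnorm(
            x, self.gamma, self.beta, mean, var, training=ctx.training
        )


class ReLU(Module):
    def forward(self, x, ctx):
        return ag.relu(x)


class MaxPool2x2(Module):
    def forward(self, x, ctx):
        return ag.maxpool2x2(x)


class Dropout(Module):
    """Element-wise Bernoulli dropout, active only in training/stochastic mode."""

    def __init__(self, p: float):
        if not 0.0 < p < 1.0:
            raise ValueError(f"dropout rate must be in (0,1), got {p}")
        self.p = p

    def forward(self, x, ctx):
        if not ctx.dropout_active:
            return x
        if ctx.rng is None:
            raise ValueError("dropout requires a seeded rng in the forward context")
        return ag.dropout(x, self.p, ctx.rng)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x, ctx):
        for m in self.mods:
            x = m.forward(x, ctx)
        return x


@dataclass
class Adam:
    """Adam optimizer over a fixed parameter list."""

    params: list
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: list = field(default_factory=list)
    v: list = field(default_factory=list)

    def __post_init__(self):
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
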