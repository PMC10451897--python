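"""Minimal neural-network layer zoo on top of :mod:`milct.autodiff`.

Modules register parameters by name; ``named_parameters`` walks child
modules (attributes that are Modules or lists of Modules) recursively,
which gives deterministic parameter ordering for the optimizer and for
checkpoint round-trips.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import truncnorm

from .autodiff import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "Adam", "trunc_normal"]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated-normal init on [-2 std, 2 std], the ViT convention."""
    return truncnorm.rvs(-2.0, 2.0, scale=std, size=shape, random_state=rng)


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}

    def param(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(data, dtype=np.float64))
        self._params[name] = t
        return t

    def _children(self):
        for name, value in vars(self).items():
            if name == "_params":
                continue
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, t in self._params.items():
            yield prefix + name, t
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [t for _, t in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, t in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {arr.shape} vs {t.data.shape}"
                )
            t.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map y = x W^T + b on the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.weight = self.param("weight", trunc_normal(rng, (d_out, d_in)))
        self.bias = self.param("bias", np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.d_in:
            raise ValueError(f"expected last dim {self.d_in}, got {x.shape[-1]}")
        y = x @ self.weight.swapaxes(0, 1)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    """Per-token normalization over the channel axis with affine gain/offset."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.dim, self.eps = dim, eps
        self.gamma = self.param("gamma", np.ones(dim))
        self.beta = self.param("beta", np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Adam:
    """Adam with L2 weight decay (gradient-coupled, classic form)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
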