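"""Minimal NumPy neural-network primitives with manual backpropagation.

Just enough machinery for the hierarchical window-attention classifier:
linear layers, layer normalization, GELU, dropout, softmax cross-entropy
and an Adam optimizer. Every module caches what its backward pass needs
during ``forward`` and accumulates parameter gradients in ``backward``;
``parameters()`` yields :class:`Parameter` objects shared with the
optimizer. All floating-point work is float32.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

DTYPE = np.float32


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) samples with |x| > 2*std redrawn (truncated normal)."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x.astype(DTYPE)


class Module:
    """Base class: children are discovered from instance attributes."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    """Affine map on the last axis: y = x @ W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, std: float = 0.02):
        self.W = Parameter(trunc_normal(rng, (d_in, d_out), std), "W")
        self.b = Parameter(np.zeros(d_out), "b") if bias else None
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        d_in, d_out = self.W.value.shape
        self.W.grad += x.reshape(-1, d_in).T @ dy.reshape(-1, d_out)
        if self.b is not None:
            self.b.grad += dy.reshape(-1, d_out).sum(axis=0)
        return dy @ self.W.value.T


class LayerNorm(Module):
    """Normalization over the last axis with learnable scale and shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim), "gamma")
        self.beta = Parameter(np.zeros(dim), "beta")
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return (self.gamma.value * xhat + self.beta.value).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = xhat.shape[-1]
        self.gamma.grad += (dy * xhat).reshape(-1, n).sum(axis=0)
        self.beta.grad += dy.reshape(-1, n).sum(axis=0)
        dxhat = dy * self.gamma.value
        return (inv / n * (
            n * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )).astype(DTYPE)


class GELU(Module):
    """Exact Gaussian-error linear unit, 0.5*x*(1 + erf(x/sqrt(2)))."""

    def __init__(self):
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return (0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
        return (dy * (cdf + x * pdf)).astype(DTYPE)


class Dropout(Module):
    """Inverted dropout; identity when ``p == 0`` or in inference mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p)
                      / (1.0 - self.p)).astype(DTYPE)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray,
                  weights: np.ndarray | None = None):
    """Mean softmax cross-entropy.

    Returns ``(loss, dlogits)``; ``weights`` optionally reweights classes.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    w = np.ones(n) if weights is None else weights[labels]
    logp = np.log(np.clip(p[np.arange(n), labels], 1e-30, None))
    loss = float(-(w * logp).sum() / w.sum())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (w / w.sum())[:, None]
    return loss, dlogits.astype(DTYPE)


class Adam:
    """Adam with bias correction (Kingma & Ba defaults configurable)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
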