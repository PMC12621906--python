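"""Minimal feed-forward network primitives with explicit backpropagation.

The embedding model is small (a few fully-connected layers), so rather than
pulling in a deep-learning framework the forward and backward passes are
written directly in numpy. Layers cache their inputs during ``forward`` and
consume them in ``backward``; parameters are plain float64 arrays updated by
:class:`RMSProp`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Linear", "CELU", "Identity", "Sequential", "RMSProp", "kaiming_uniform"]


def kaiming_uniform(n_in: int, n_out: int, rng: np.random.Generator) -> np.ndarray:
    """Kaiming-uniform fan-in initialization: U(-sqrt(6/fan_in), +)."""
    bound = np.sqrt(6.0 / n_in)
    return rng.uniform(-bound, bound, size=(n_in, n_out))


class Linear:
    """Affine layer ``x @ W + b`` with zero-initialized bias."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = kaiming_uniform(n_in, n_out, rng)
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class CELU:
    """celu(v) = max(0, v) + min(0, alpha * (exp(v / alpha) - 1))."""

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        a = self.alpha
        return np.maximum(0.0, x) + np.minimum(0.0, a * np.expm1(x / a))

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        return g * np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0) / self.alpha))

    def params(self):
        return []


class Identity:
    """Pass-through activation (used by the wiring-oracle test mode)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g

    def params(self):
        return []


class Sequential:
    """A chain of layers with symmetric forward/backward traversal."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[tuple[str, Linear]]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def linears(self) -> list[Linear]:
        return [l for l in self.layers if isinstance(l, Linear)]


class RMSProp:
    """RMSProp with smoothing constant ``alpha`` (lr=0.001, alpha=0.9 defaults).

    v <- alpha * v + (1 - alpha) * g**2 ; p <- p - lr * g / (sqrt(v) + eps)
    """

    def __init__(self, params: list[tuple[str, Linear]], lr: float = 0.001,
                 alpha: float = 0.9, eps: float = 1e-8):
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.params = params
        self.state = [np.zeros_like(getattr(layer, name)) for name, layer in params]

    def step(self) -> None:
        for (name, layer), v in zip(self.params, self.state):
            g = getattr(layer, "g" + name)
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            getattr(layer, name)[...] -= self.lr * g / (np.sqrt(v) + self.eps)
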