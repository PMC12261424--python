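"""NumPy neural-network primitives with explicit backward passes.

Each module caches the activations it needs during ``forward`` and
consumes them in a single subsequent ``backward`` call (one backward per
forward). Gradients accumulate into ``Parameter.grad``; the optimizer
zeroes them between steps. Compute dtype is set per layer at
construction (the encoder passes its configured dtype); runs are
bit-reproducible at a fixed thread count.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name", "trainable")

    def __init__(self, value: np.ndarray, name: str = "",
                 trainable: bool = True) -> None:
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.trainable = trainable

    @property
    def size(self) -> int:
        return self.value.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name}, shape={self.value.shape})"


class Linear:
    """Affine map on the last axis: y = x W + b, W of shape (d_in, d_out)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 init_std: float = 0.02, name: str = "linear",
                 dtype=np.float64) -> None:
        self.W = Parameter(rng.normal(0.0, init_std, (d_in, d_out))
                           .astype(dtype), f"{name}.W")
        self.b = Parameter(np.zeros(d_out, dtype=dtype), f"{name}.b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, d: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = d.reshape(-1, d.shape[-1])
        if self.W.trainable:
            self.W.grad += x2.T @ d2
        if self.b.trainable:
            self.b.grad += d2.sum(axis=0)
        return d @ self.W.value.T

    def effective_weight(self) -> np.ndarray:
        return self.W.value

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class LoRALinear:
    """Low-rank adapted linear layer: y = x (W + B A) + b.

    The base weight W (m x n) and bias are frozen; only the factors
    B (m x r) and A (r x n) train, for r(m + n) trainable values per
    target instead of m*n. B starts at zero so the wrapped layer is
    forward-identical to its base until the first update. ``scale``
    multiplies the update (conventionally alpha / rank).
    """

    def __init__(self, base: Linear, rank: int,
                 rng: np.random.Generator, name: str = "lora",
                 scale: float = 1.0) -> None:
        m, n = base.W.value.shape
        if rank < 1:
            raise ValueError("LoRA rank must be >= 1")
        if rank > min(m, n):
            raise ValueError(
                f"rank {rank} exceeds min dimension of a {m}x{n} weight")
        if rank == min(m, n):
            import logging
            logging.getLogger(__name__).warning(
                "LoRA rank %d equals min(%d, %d): the adaptation is "
                "full-rank, not low-rank", rank, m, n)
        self.base = base
        base.W.trainable = False
        base.b.trainable = False
        dtype = base.W.value.dtype
        self.B = Parameter(np.zeros((m, rank), dtype=dtype), f"{name}.B")
        self.A = Parameter(rng.normal(0.0, 1.0 / rank, (rank, n))
                           .astype(dtype), f"{name}.A")
        self.scale = float(scale)
        self._x: np.ndarray | None = None
        self._xB: np.ndarray | None = None

    @property
    def rank(self) -> int:
        return self.B.value.shape[1]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._xB = x @ self.B.value
        return (x @ self.base.W.value + self.base.b.value
                + self.scale * (self._xB @ self.A.value))

    def backward(self, d: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = d.reshape(-1, d.shape[-1])
        xB2 = self._xB.reshape(-1, self.rank)
        dxB = self.scale * (d @ self.A.value.T)
        self.A.grad += self.scale * (xB2.T @ d2)
        self.B.grad += x2.T @ dxB.reshape(-1, self.rank)
        return d @ self.base.W.value.T + dxB @ self.B.value.T

    def effective_weight(self) -> np.ndarray:
        return self.base.W.value + self.scale * (self.B.value @ self.A.value)

    def parameters(self) -> list[Parameter]:
        return [self.base.W, self.base.b, self.B, self.A]


class LayerNorm:
    """Layer normalization over the last axis with learned gain and bias."""

    def __init__(self, d: int, name: str = "ln", eps: float = 1e-12,
                 dtype=np.float64) -> None:
        self.g = Parameter(np.ones(d, dtype=dtype), f"{name}.g")
        self.b = Parameter(np.zeros(d, dtype=dtype), f"{name}.b")
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        return self.g.value * self._xhat + self.b.value

    def backward(self, d: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        dxhat = d * self.g.value
        self.g.grad += (d * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.b.grad += d.reshape(-1, d.shape[-1]).sum(axis=0)
        mean_dxhat = dxhat.mean(axis=-1, keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return self._inv_std * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)

    def parameters(self) -> list[Parameter]:
        return [self.g, self.b]


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian error linear unit."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * phi


class GELU:
    def __init__(self) -> None:
        self._x: np.ndarray | None = None
        self._cdf: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / _SQRT2))  # reused in backward
        return x * self._cdf

    def backward(self, d: np.ndarray) -> np.ndarray:
        x = self._x
        phi = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return d * (self._cdf + x * phi)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=axis, keepdims=True)
    return z


# -- rotary position embedding -------------------------------------------


def rope_angles(positions: np.ndarray, dim: int,
                theta: float) -> tuple[np.ndarray, np.ndarray]:
    """cos/sin tables of shape (len(positions), dim//2) for rotary pairs.

    Pair j at position t rotates by angle t * theta^(-2j/dim).
    """
    if dim % 2:
        raise ValueError("rotary dimension must be even")
    j = np.arange(dim // 2)
    inv_freq = theta ** (-2.0 * j / dim)
    ang = np.asarray(positions, dtype=np.float64)[:, None] * inv_freq[None, :]
    return np.cos(ang), np.sin(ang)


def rope_rotate(x: np.ndarray, cos: np.ndarray, sin: np.ndarray,
                inverse: bool = False) -> np.ndarray:
    """Rotate consecutive coordinate pairs of ``x`` (..., L, dim).

    ``inverse=True`` applies the transpose rotation, which is also the
    exact backward pass (rotations are orthogonal).
    """
    if inverse:
        sin = -sin
    x_even = x[..., 0::2]
    x_odd = x[..., 1::2]
    out = np.empty_like(x)
    out[..., 0::2] = x_even * cos - x_odd * sin
    out[..., 1::2] = x_even * sin + x_odd * cos
    return out


def apply_rope(x: np.ndarray, positions: np.ndarray,
               theta: float = 10000.0) -> np.ndarray:
    """Rotate query/key vectors (..., L, dim) by their position angles."""
    cos, sin = rope_angles(positions, x.shape[-1], theta)
    return rope_rotate(x, cos, sin)
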