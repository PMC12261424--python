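"""Transformer encoder over probability-matrix inputs.

Instead of a token-lookup embedding, the input is a column-stochastic
9xL matrix and the embedding is a linear map: each column's embedding is
the probability-weighted sum of the nine symbol embeddings, which reduces
to classical table lookup exactly when the column is one-hot. Positions
enter through rotary embeddings (RoPE); at evaluation lengths beyond the
pretraining context the rotary base is enlarged by dynamic NTK scaling so
relative angles interpolate rather than extrapolate. Blocks are pre-norm
(LN -> sublayer -> residual) with a final LayerNorm, and the MLM head is
a dense transform + GELU + LayerNorm + decoder over the vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..vocab import VOCAB_SIZE
from .layers import (GELU, LayerNorm, Linear, Parameter, rope_angles,
                     rope_rotate, softmax)

#: documented hard cap on input length (relative angles degrade far beyond
#: the NTK-scaled regime; raise deliberately, not silently)
MAX_CONTEXT = 32768


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The default geometry (12 layers, hidden 768, 12 heads, inner 3072,
    9-symbol vocabulary) is the standard base-encoder shape; its exact
    trainable-parameter sum rounds to 86 million.
    """

    num_layers: int = 12
    hidden_size: int = 768
    num_heads: int = 12
    intermediate_size: int = 3072
    vocab_size: int = VOCAB_SIZE
    train_context: int = 512
    dropout: float = 0.0
    nucleotide_only_head: bool = False
    init_std: float = 0.02
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.hidden_size % self.num_heads:
            raise ValueError("hidden_size must be divisible by num_heads")
        if self.head_dim % 2:
            raise ValueError("per-head dimension must be even for RoPE")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    @property
    def head_dim(self) -> int:
        return self.hidden_size // self.num_heads

    @property
    def head_vocab(self) -> int:
        return 4 if self.nucleotide_only_head else self.vocab_size


@dataclass
class RopeConfig:
    """Rotary positional-encoding parameters.

    ``theta0`` is the base frequency, ``alpha0`` the initial NTK scaling
    parameter. The effective scale alpha is always 1 at or below the
    pretraining context length.
    """

    theta0: float = 10000.0
    alpha0: float = 1.0

    def __post_init__(self) -> None:
        if self.theta0 <= 0:
            raise ValueError("theta0 must be positive")
        if self.alpha0 < 1:
            raise ValueError("alpha0 must be >= 1")


def dynamic_ntk_alpha(l_test: int, l_train: int, alpha0: float = 1.0) -> float:
    """NTK scale factor: 1 within the pretraining context, otherwise
    alpha0 * (l_test / l_train) - (alpha0 - 1)."""
    if l_test < 1 or l_train < 1:
        raise ValueError("lengths must be positive")
    if alpha0 < 1:
        raise ValueError("alpha0 must be >= 1")
    if l_test <= l_train:
        return 1.0
    return alpha0 * (l_test / l_train) - (alpha0 - 1.0)


def ntk_scaled_base(theta0: float, alpha: float, dim: int) -> float:
    """Rescaled rotary base theta = theta0 * alpha^(dim / (dim - 2))."""
    if dim <= 2:
        raise ValueError("rotary dimension must exceed 2")
    if dim % 2:
        raise ValueError("rotary dimension must be even")
    return theta0 * alpha ** (dim / (dim - 2.0))


def embed_probabilistic(matrix: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Probability-weighted symbol embeddings: (9, L) x (9, d) -> (L, d).

    Column c maps to sum_s matrix[s, c] * table[s]; on one-hot columns
    this is exactly table lookup.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    table = np.asarray(table, dtype=np.float64)
    if matrix.shape[0] != table.shape[0]:
        raise ValueError(
            f"matrix has {matrix.shape[0]} rows but table has "
            f"{table.shape[0]} symbol embeddings")
    sums = matrix.sum(axis=0)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("input columns must sum to 1")
    return matrix.T @ table


class _Dropout:
    def __init__(self, p: float) -> None:
        self.p = p
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, rng: np.random.Generator | None):
        if self.p == 0.0 or rng is None:
            self._mask = 1.0
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, d: np.ndarray) -> np.ndarray:
        return d * self._mask


class MultiHeadAttention:
    """Exact scaled-dot-product attention with rotary positions."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 name: str) -> None:
        d = config.hidden_size
        self.config = config
        dt = config.np_dtype
        self.query = Linear(d, d, rng, config.init_std, f"{name}.query", dt)
        self.key = Linear(d, d, rng, config.init_std, f"{name}.key", dt)
        self.value = Linear(d, d, rng, config.init_std, f"{name}.value", dt)
        self.output = Linear(d, d, rng, config.init_std, f"{name}.output", dt)

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, L, _ = x.shape
        h, dh = self.config.num_heads, self.config.head_dim
        return x.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, h, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, h * dh)

    def forward(self, x: np.ndarray, bias: np.ndarray,
                cos: np.ndarray, sin: np.ndarray) -> np.ndarray:
        dh = self.config.head_dim
        q = rope_rotate(self._split(self.query.forward(x)), cos, sin)
        k = rope_rotate(self._split(self.key.forward(x)), cos, sin)
        v = self._split(self.value.forward(x))
        scores = q @ k.swapaxes(-1, -2) / np.sqrt(dh) + bias
        attn = softmax(scores)
        ctx = attn @ v
        self._cache = (q, k, v, attn, cos, sin)
        return self.output.forward(self._merge(ctx))

    def backward(self, d: np.ndarray) -> np.ndarray:
        q, k, v, attn, cos, sin = self._cache
        dh = self.config.head_dim
        dctx = self._split(self.output.backward(d))
        dattn = dctx @ v.swapaxes(-1, -2)
        dv = attn.swapaxes(-1, -2) @ dctx
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(dh)
        dq = dscores @ k
        dk = dscores.swapaxes(-1, -2) @ q
        dq = rope_rotate(dq, cos, sin, inverse=True)
        dk = rope_rotate(dk, cos, sin, inverse=True)
        dx = self.query.backward(self._merge(dq))
        dx += self.key.backward(self._merge(dk))
        dx += self.value.backward(self._merge(dv))
        return dx

    def parameters(self) -> list[Parameter]:
        return [p for lin in (self.query, self.key, self.value, self.output)
                for p in lin.parameters()]


class EncoderBlock:
    """Pre-norm transformer block: x + Attn(LN(x)), then x + FFN(LN(x))."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 name: str) -> None:
        d, inner = config.hidden_size, config.intermediate_size
        dt = config.np_dtype
        self.ln1 = LayerNorm(d, f"{name}.ln1", dtype=dt)
        self.attn = MultiHeadAttention(config, rng, f"{name}.attn")
        self.drop1 = _Dropout(config.dropout)
        self.ln2 = LayerNorm(d, f"{name}.ln2", dtype=dt)
        self.ffn_in = Linear(d, inner, rng, config.init_std, f"{name}.ffn_in",
                             dt)
        self.act = GELU()
        self.ffn_out = Linear(inner, d, rng, config.init_std,
                              f"{name}.ffn_out", dt)
        self.drop2 = _Dropout(config.dropout)

    def forward(self, x, bias, cos, sin, rng=None):
        x = x + self.drop1.forward(
            self.attn.forward(self.ln1.forward(x), bias, cos, sin), rng)
        x = x + self.drop2.forward(
            self.ffn_out.forward(self.act.forward(
                self.ffn_in.forward(self.ln2.forward(x)))), rng)
        return x

    def backward(self, d):
        dffn = self.drop2.backward(d)
        dffn = self.ffn_in.backward(self.act.backward(
            self.ffn_out.backward(dffn)))
        d = d + self.ln2.backward(dffn)
        dattn = self.attn.backward(self.drop1.backward(d))
        return d + self.ln1.backward(dattn)

    def parameters(self) -> list[Parameter]:
        return (self.ln1.parameters() + self.attn.parameters()
                + self.ln2.parameters() + self.ffn_in.parameters()
                + self.ffn_out.parameters())


class ProbEncoder:
    """The full encoder: linear embedding, rotary blocks, MLM head."""

    def __init__(self, config: ModelConfig,
                 rope: RopeConfig | None = None,
                 seed: int = 0) -> None:
        self.config = config
        self.rope = rope or RopeConfig()
        rng = np.random.default_rng(seed)
        d = config.hidden_size
        dt = config.np_dtype
        self.embed = Linear(config.vocab_size, d, rng, config.init_std,
                            "embed", dt)
        self.blocks = [EncoderBlock(config, rng, f"block{i}")
                       for i in range(config.num_layers)]
        self.final_ln = LayerNorm(d, "final_ln", dtype=dt)
        self.head_transform = Linear(d, d, rng, config.init_std,
                                     "head.transform", dt)
        self.head_act = GELU()
        self.head_ln = LayerNorm(d, "head.ln", dtype=dt)
        self.decoder = Linear(d, config.head_vocab, rng, config.init_std,
                              "head.decoder", dt)
        self._hidden: np.ndarray | None = None

    # -- bookkeeping -----------------------------------------------------

    def parameters(self) -> list[Parameter]:
        params = self.embed.parameters()
        for blk in self.blocks:
            params += blk.parameters()
        params += self.final_ln.parameters()
        params += self.head_transform.parameters()
        params += self.head_ln.parameters()
        params += self.decoder.parameters()
        return params

    def named_parameters(self) -> dict[str, Parameter]:
        return {p.name: p for p in self.parameters()}

    def trainable_parameter_count(self) -> int:
        return sum(p.size for p in self.parameters() if p.trainable)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def attention_linears(self) -> dict[str, tuple[object, str]]:
        """Addressable linear sublayers for LoRA wrapping:
        name -> (owner object, attribute name)."""
        out: dict[str, tuple[object, str]] = {}
        for i, blk in enumerate(self.blocks):
            for attr in ("query", "key", "value", "output"):
                out[f"block{i}.attn.{attr}"] = (blk.attn, attr)
            out[f"block{i}.ffn_in"] = (blk, "ffn_in")
            out[f"block{i}.ffn_out"] = (blk, "ffn_out")
        return out

    # -- forward / backward ----------------------------------------------

    def _rope_tables(self, length: int, l_test: int | None):
        l_test = length if l_test is None else l_test
        alpha = dynamic_ntk_alpha(l_test, self.config.train_context,
                                  self.rope.alpha0)
        theta = ntk_scaled_base(self.rope.theta0, alpha, self.config.head_dim)
        return rope_angles(np.arange(length), self.config.head_dim, theta)

    def forward(self, matrices: np.ndarray,
                attn_mask: np.ndarray | None = None,
                l_test: int | None = None,
                training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Run the encoder and MLM head.

        Parameters
        ----------
        matrices:
            (B, 9, L) or (9, L) column-stochastic input.
        attn_mask:
            (B, L) boolean, True where attention may look (padding is
            False). Defaults to all-True.
        l_test:
            Evaluation context length driving NTK scaling; defaults to L.

        Returns per-position logits (B, L, head_vocab).
        """
        x = np.asarray(matrices, dtype=self.config.np_dtype)
        if x.ndim == 2:
            x = x[None]
        B, V, L = x.shape
        if V != self.config.vocab_size:
            raise ValueError(f"expected {self.config.vocab_size} symbol "
                             f"rows, got {V}")
        if L > MAX_CONTEXT:
            raise ValueError(f"input length {L} exceeds hard cap {MAX_CONTEXT}")
        colsum = x.sum(axis=1)
        if attn_mask is None:
            attn_mask = np.ones((B, L), dtype=bool)
        if np.any(np.abs(colsum[attn_mask] - 1.0) > 1e-6):
            raise ValueError("input columns must sum to 1")
        bias = np.where(attn_mask[:, None, None, :], 0.0,
                        -np.inf).astype(self.config.np_dtype)
        cos, sin = self._rope_tables(L, l_test)
        cos = cos.astype(self.config.np_dtype)
        sin = sin.astype(self.config.np_dtype)
        drop_rng = rng if training else None

        h = self.embed.forward(x.transpose(0, 2, 1))
        for blk in self.blocks:
            h = blk.forward(h, bias, cos, sin, drop_rng)
        h = self.final_ln.forward(h)
        self._hidden = h
        t = self.head_ln.forward(self.head_act.forward(
            self.head_transform.forward(h)))
        return self.decoder.forward(t)

    def hidden_states(self) -> np.ndarray:
        """Final-layer (post-norm, pre-head) states from the last forward."""
        if self._hidden is None:
            raise RuntimeError("no forward pass has been run")
        return self._hidden

    def backward(self, dlogits: np.ndarray,
                 dhidden: np.ndarray | None = None) -> None:
        """Backpropagate a logit gradient (and optionally an extra
        gradient on the final hidden states)."""
        d = self.head_ln.backward(self.decoder.backward(dlogits))
        d = self.head_transform.backward(self.head_act.backward(d))
        if dhidden is not None:
            d = d + dhidden
        d = self.final_ln.backward(d)
        for blk in reversed(self.blocks):
            d = blk.backward(d)
        self.embed.backward(d)


def forward_mlm(model: ProbEncoder, matrices: np.ndarray,
                attn_mask: np.ndarray | None = None,
                l_test: int | None = None) -> np.ndarray:
    """Evaluation-mode forward pass returning per-position probability
    distributions over the vocabulary (rows sum to 1)."""
    logits = model.forward(matrices, attn_mask=attn_mask, l_test=l_test,
                           training=False)
    return softmax(logits)


def count_parameters(config: ModelConfig) -> int:
    """Exact trainable-parameter count of :class:`ProbEncoder` for a
    config, by shape enumeration (no allocation)."""
    d, inner, v = (config.hidden_size, config.intermediate_size,
                   config.vocab_size)
    embed = v * d + d
    per_layer = (
        4 * (d * d + d)          # query/key/value/output projections
        + 2 * 2 * d              # two layer norms
        + (d * inner + inner)    # feed-forward in
        + (inner * d + d)        # feed-forward out
    )
    head = (d * d + d) + 2 * d + (d * config.head_vocab + config.head_vocab)
    final_ln = 2 * d
    return embed + config.num_layers * per_layer + final_ln + head
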