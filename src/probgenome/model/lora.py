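"""Low-rank adaptation of encoder linear layers.

Fine-tuning replaces selected linear weights W (m x n) with W + B A,
where B (m x r) starts at zero and A (r x n) trains alongside it; the
base weights freeze. The wrapped model is forward-identical to its base
until the first update, and each target contributes r(m + n) trainable
values instead of m*n.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass

import numpy as np

from .encoder import ProbEncoder
from .layers import Linear, LoRALinear


@dataclass
class LoraSpec:
    """Which linears to adapt and at what rank.

    ``targets`` are fnmatch-style patterns over the encoder's addressable
    linear names (e.g. ``"*.attn.query"``, ``"*.attn.value"``).
    """

    rank: int = 8
    alpha: float = 8.0
    targets: tuple[str, ...] = ("*.attn.query", "*.attn.value")

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def lora_wrap(model: ProbEncoder, spec: LoraSpec,
              seed: int = 0) -> list[LoRALinear]:
    """Swap matching linears for :class:`LoRALinear` in place.

    All non-adapted parameters (including the embedding, layer norms and
    MLM head) are frozen, so only the A/B factors train afterwards.
    Returns the wrapped layers.
    """
    rng = np.random.default_rng(seed)
    addressable = model.attention_linears()
    matched = {name: loc for name, loc in addressable.items()
               if any(fnmatch.fnmatch(name, pat) for pat in spec.targets)}
    if not matched:
        raise ValueError(f"no linears match targets {spec.targets}")
    for p in model.parameters():
        p.trainable = False
    wrapped: list[LoRALinear] = []
    for name, (owner, attr) in matched.items():
        base = getattr(owner, attr)
        if not isinstance(base, Linear):
            raise TypeError(f"{name} is not a plain Linear")
        adapter = LoRALinear(base, spec.rank, rng, name=f"{name}.lora",
                             scale=spec.alpha / spec.rank)
        setattr(owner, attr, adapter)
        wrapped.append(adapter)
    return wrapped


def lora_trainable_count(m: int, n: int, rank: int) -> int:
    """Trainable values for one adapted m x n weight: r(m + n)."""
    return rank * (m + n)
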