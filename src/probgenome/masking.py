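"""SNV-prioritized masking and temperature-scaled soft targets.

The pretraining objective hides 15% of genomic columns per window,
preferring columns with observed variation: variant columns are exhausted
first, and only then are invariant columns drawn to fill the quota.
Selected columns are replaced by a one-hot [MASK] column 80% of the time
and left as their original probabilistic distribution otherwise. The
training target at every selected column is the original allele
distribution sharpened (or flattened) by temperature scaling over its
support, embedded in the 9-symbol space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidWindowError
from .vocab import MASK, NUC_SLICE, VOCAB_SIZE
from .windows import EncodedWindow

LOG_FLOOR = 1e-12


@dataclass
class MaskingPolicy:
    """Masking and soft-target hyperparameters.

    ``temperature`` < 1 sharpens target distributions, > 1 flattens them;
    0.7 is the pretraining default. ``scale_mode="off"`` bypasses
    temperature scaling entirely (raw allele distributions as targets),
    which is not the same as ``temperature=1``: a softmax at temperature 1
    is not the identity map.
    """

    mask_ratio: float = 0.15
    mask_replace_prob: float = 0.8
    keep_prob: float = 0.2
    temperature: float = 0.7
    scale_mode: str = "softmax"

    def __post_init__(self) -> None:
        if not 0.0 < self.mask_ratio < 1.0:
            raise ValueError("mask_ratio must be in (0,1)")
        if abs(self.mask_replace_prob + self.keep_prob - 1.0) > 1e-12:
            raise ValueError("mask_replace_prob + keep_prob must equal 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.scale_mode not in ("softmax", "off"):
            raise ValueError(f"unknown scale_mode {self.scale_mode!r}")


@dataclass
class MlmExample:
    """One masked training example: post-mask input, chosen columns, and
    the 9-symbol soft targets derived from the pre-mask columns."""

    input_matrix: np.ndarray        # (9, L)
    selected_positions: np.ndarray  # (k,) sorted column indices
    targets: np.ndarray             # (k, 9), mass only on nucleotide rows


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def round_half_up(x: float) -> int:
    """Deterministic rounding used for the masking quota."""
    return int(math.floor(x + 0.5))


def select_mask_positions(window: EncodedWindow, policy: MaskingPolicy,
                          seed=0) -> np.ndarray:
    """Choose the columns whose contents the model must predict.

    The quota is ``round-half-up(mask_ratio * L_eff)`` over the genomic
    (non-special) columns. If variant columns alone meet the quota, the
    selection is drawn uniformly from them; otherwise every variant
    column is taken and invariant columns are drawn uniformly to fill
    the remainder. Special columns are never selected.
    """
    rng = _as_rng(seed)
    l_eff = window.n_effective
    if l_eff < 1:
        raise InvalidWindowError("window has no genomic columns")
    k = round_half_up(policy.mask_ratio * l_eff)
    if k > l_eff:
        raise InvalidWindowError(
            f"mask quota {k} exceeds {l_eff} genomic columns")
    snv_idx = np.flatnonzero(window.is_snv)
    if len(snv_idx) >= k:
        chosen = rng.choice(snv_idx, size=k, replace=False)
    else:
        pool = np.flatnonzero(~window.is_special & ~window.is_snv)
        extra = rng.choice(pool, size=k - len(snv_idx), replace=False)
        chosen = np.concatenate([snv_idx, extra])
    return np.sort(chosen.astype(np.int64))


def temperature_scale(q: np.ndarray, tau: float) -> np.ndarray:
    """Softmax of q/tau restricted to q's support.

    Zero entries stay exactly zero, so one-hot distributions are fixed
    points for every temperature; as tau grows the output tends to the
    uniform distribution over the support.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    q = np.asarray(q, dtype=np.float64)
    support = q > 0
    if not support.any():
        raise ValueError("cannot temperature-scale an all-zero vector")
    out = np.zeros_like(q)
    z = q[support] / tau
    z = z - z.max()  # shift-invariant; guards overflow
    e = np.exp(z)
    out[support] = e / e.sum()
    return out


def make_target(column: np.ndarray, policy: MaskingPolicy) -> np.ndarray:
    """9-symbol soft target for one pre-mask column: the nucleotide block
    temperature-scaled, zero mass on special rows."""
    nuc = np.asarray(column, dtype=np.float64)[NUC_SLICE]
    target = np.zeros(VOCAB_SIZE)
    if policy.scale_mode == "off":
        target[NUC_SLICE] = nuc / nuc.sum()
    else:
        target[NUC_SLICE] = temperature_scale(nuc, policy.temperature)
    return target


def apply_mask(window: EncodedWindow, selected_positions: np.ndarray,
               policy: MaskingPolicy, seed=0) -> MlmExample:
    """Mask the selected columns and build their soft targets.

    Per selected column, independently: with probability
    ``mask_replace_prob`` the input column becomes a one-hot [MASK]
    column; otherwise it is left as its original distribution. Targets
    always derive from the pre-mask column, never from the masked input.
    """
    rng = _as_rng(seed)
    selected = np.asarray(selected_positions, dtype=np.int64)
    if len(selected) and (selected.min() < 0 or selected.max() >= window.L):
        raise IndexError("selected position out of range")
    if window.is_special[selected].any():
        raise InvalidWindowError("special columns cannot be masked")
    input_matrix = window.matrix.copy()
    targets = np.empty((len(selected), VOCAB_SIZE))
    replace = rng.random(len(selected)) < policy.mask_replace_prob
    for i, pos in enumerate(selected):
        targets[i] = make_target(window.matrix[:, pos], policy)
        if replace[i]:
            input_matrix[:, pos] = 0.0
            input_matrix[MASK, pos] = 1.0
    return MlmExample(input_matrix=input_matrix,
                      selected_positions=selected, targets=targets)


def soft_cross_entropy(p: np.ndarray, q: np.ndarray,
                       floor: float = LOG_FLOOR) -> float:
    """Cross-entropy H(q, p) = -sum_i q_i log p_i, averaged over leading
    axes when given batches.

    ``p`` is the model's predicted distribution, ``q`` the soft target;
    0*log(0) terms contribute zero, and predictions are floored at
    ``floor`` inside the log to guard exact zeros.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    logp = np.log(np.maximum(p, floor))
    per_position = -(q * logp).sum(axis=-1)
    return float(per_position.mean())
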