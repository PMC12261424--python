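"""Pretraining loop, schedule, and evaluation against planted truth.

The loop is the masked-language-modeling cycle: sample windows uniformly
from the training contigs' segment streams, mask with SNV priority,
forward, soft cross-entropy against temperature-scaled targets, AdamW
step under a linear-warmup/cosine-decay schedule. Evaluation reports the
mean masked-position loss and its exponential (perplexity), and — the
operational test of the method — how well a model probed with [MASK] at
a planted variant locus recovers the planted allele distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import ProbabilisticGenome
from .masking import (LOG_FLOOR, MaskingPolicy, apply_mask,
                      select_mask_positions, soft_cross_entropy,
                      temperature_scale)
from .model.encoder import ProbEncoder, forward_mlm
from .model.layers import softmax
from .model.optim import AdamW, clip_gradients
from .model.checkpoint import save_checkpoint
from .vocab import MASK, NUC_SLICE, PAD, VOCAB_SIZE
from .windows import EncodedWindow, encode_window

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Pretraining hyperparameters.

    The optimizer constants (AdamW beta1=0.9, beta2=0.99, eps=1e-8,
    weight decay 0.01; peak rate 4e-4 decaying to 1e-8) are the full-scale
    recipe; batch size, step count, and window length default to desk
    scale. Warmup defaults to total_steps/12, preserving the full-scale
    schedule's shape (10k of 120k steps).
    """

    batch_size: int = 32
    total_steps: int = 2000
    warmup_steps: int | None = None
    peak_lr: float = 4e-4
    final_lr: float = 1e-8
    betas: tuple[float, float] = (0.9, 0.99)
    eps: float = 1e-8
    weight_decay: float = 0.01
    seed: int = 0
    holdout_contigs: tuple[str, ...] = ()
    window_length: int = 128
    grad_clip: float | None = None
    log_every: int = 100
    checkpoint_every: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.warmup_steps is None:
            self.warmup_steps = max(1, self.total_steps // 12)
        if not 0 < self.warmup_steps < self.total_steps:
            raise ValueError("need 0 < warmup_steps < total_steps")
        if self.peak_lr <= self.final_lr:
            raise ValueError("peak_lr must exceed final_lr")


def lr_schedule(step: int, config: TrainConfig) -> float:
    """Learning rate at ``step`` in [0, total_steps]: linear 0 -> peak
    over warmup, then cosine peak -> final over the remaining steps."""
    if not 0 <= step <= config.total_steps:
        raise ValueError(f"step {step} outside [0, {config.total_steps}]")
    w = config.warmup_steps
    if step <= w:
        return config.peak_lr * step / w
    frac = (step - w) / (config.total_steps - w)
    return (config.final_lr + 0.5 * (config.peak_lr - config.final_lr)
            * (1.0 + math.cos(math.pi * frac)))


class WindowSampler:
    """Uniform window starts over the training contigs' segment streams.

    Hold-out contigs are excluded entirely; contigs are weighted by their
    number of valid starts so every eligible window is equally likely.
    """

    def __init__(self, pg: ProbabilisticGenome, window_length: int,
                 holdout_contigs: tuple[str, ...] = ()) -> None:
        self.pg = pg
        self.window_length = window_length
        self.contigs = [
            c for c in pg.reference.contigs
            if c not in holdout_contigs
            and pg.reference.stream_length(c) >= window_length]
        if not self.contigs:
            raise ValueError("no training contig can hold a window of "
                             f"length {window_length}")
        starts = np.array(
            [pg.reference.stream_length(c) - window_length + 1
             for c in self.contigs], dtype=np.float64)
        self._probs = starts / starts.sum()
        self._starts = starts.astype(np.int64)

    def sample(self, rng: np.random.Generator) -> tuple[str, int]:
        ci = int(rng.choice(len(self.contigs), p=self._probs))
        start = int(rng.integers(0, self._starts[ci]))
        return self.contigs[ci], start


def _collate(examples, windows) -> tuple[np.ndarray, np.ndarray, list]:
    """Pad a list of MlmExamples to a common length with [PAD] columns.

    Returns (batch (B,9,Lmax), attention mask (B,Lmax), and per-example
    (positions, targets) index lists)."""
    L = max(ex.input_matrix.shape[1] for ex in examples)
    B = len(examples)
    batch = np.zeros((B, VOCAB_SIZE, L))
    batch[:, PAD, :] = 1.0
    mask = np.zeros((B, L), dtype=bool)
    meta = []
    for i, ex in enumerate(examples):
        li = ex.input_matrix.shape[1]
        batch[i, :, :li] = ex.input_matrix
        mask[i, :li] = True
        meta.append((ex.selected_positions, ex.targets))
    return batch, mask, meta


def _batch_loss_and_grad(logits: np.ndarray, meta) -> tuple[float, np.ndarray]:
    """Mean soft cross-entropy over all selected positions in the batch,
    and the matching logit gradient (zero off the selected positions)."""
    probs = softmax(logits)
    dlogits = np.zeros_like(logits)
    total = 0.0
    n = sum(len(pos) for pos, _ in meta)
    if n == 0:
        raise ValueError("no selected positions in batch")
    for i, (pos, targets) in enumerate(meta):
        p = probs[i, pos]
        total += -(targets * np.log(np.maximum(p, LOG_FLOOR))).sum()
        dlogits[i, pos] = (p - targets) / n
    return total / n, dlogits


@dataclass
class StepRecord:
    step: int
    lr: float
    loss: float


def pretrain(pg: ProbabilisticGenome, model: ProbEncoder,
             config: TrainConfig,
             policy: MaskingPolicy | None = None) -> list[StepRecord]:
    """Run the MLM pretraining loop in place on ``model``.

    Deterministic for a fixed seed and thread count. Aborts with a
    diagnostic if the loss goes non-finite. Returns the step log.
    """
    policy = policy or MaskingPolicy()
    sampler = WindowSampler(pg, config.window_length, config.holdout_contigs)
    ss = np.random.SeedSequence(config.seed)
    sample_rng, mask_rng, drop_rng = (np.random.default_rng(s)
                                      for s in ss.spawn(3))
    optimizer = AdamW(model.parameters(), lr=config.peak_lr,
                      betas=config.betas, eps=config.eps,
                      weight_decay=config.weight_decay)
    records: list[StepRecord] = []
    for step in range(1, config.total_steps + 1):
        examples, windows = [], []
        while len(examples) < config.batch_size:
            contig, start = sampler.sample(sample_rng)
            window = encode_window(pg, contig, start, config.window_length)
            selected = select_mask_positions(window, policy, mask_rng)
            if len(selected) == 0:
                continue
            examples.append(apply_mask(window, selected, policy, mask_rng))
            windows.append(window)
        batch, attn_mask, meta = _collate(examples, windows)
        logits = model.forward(batch, attn_mask=attn_mask,
                               training=True, rng=drop_rng)
        loss, dlogits = _batch_loss_and_grad(logits, meta)
        if not math.isfinite(loss):
            raise RuntimeError(
                f"training diverged at step {step}: loss={loss}")
        optimizer.zero_grad()
        model.backward(dlogits)
        if config.grad_clip:
            clip_gradients(model.parameters(), config.grad_clip)
        optimizer.lr = lr_schedule(step, config)
        optimizer.step()
        if step % config.log_every == 0 or step == 1:
            records.append(StepRecord(step, optimizer.lr, loss))
            log.info("step %d lr %.3g loss %.4f", step, optimizer.lr, loss)
        if (config.checkpoint_every and config.checkpoint_dir
                and step % config.checkpoint_every == 0):
            save_checkpoint(Path(config.checkpoint_dir) / f"step{step}.npz",
                            model, optimizer, step)
    return records


# -- evaluation ----------------------------------------------------------


@dataclass
class EvalReport:
    """Masked-position evaluation summary; perplexity is exp(mean loss)
    by construction."""

    mean_loss: float
    perplexity: float
    n_positions: int
    per_window_loss: list[float] = field(default_factory=list)


def perplexity_from_loss(mean_loss: float) -> float:
    return math.exp(mean_loss)


def evaluate_perplexity(model, eval_windows: list[EncodedWindow],
                        policy: MaskingPolicy | None = None,
                        seed: int = 0) -> EvalReport:
    """Mean soft cross-entropy over all selected positions of a frozen,
    seeded evaluation masking, plus its perplexity.

    ``model`` is a :class:`ProbEncoder` or any callable mapping
    (input matrix (9,L), column index) to a 9-symbol distribution — the
    callable form admits oracle predictors in tests.
    """
    policy = policy or MaskingPolicy()
    rng = np.random.default_rng(seed)
    total = 0.0
    n = 0
    per_window = []
    for window in eval_windows:
        selected = select_mask_positions(window, policy, rng)
        if len(selected) == 0:
            continue
        ex = apply_mask(window, selected, policy, rng)
        if callable(model) and not isinstance(model, ProbEncoder):
            p = np.stack([model(ex.input_matrix, c)
                          for c in ex.selected_positions])
        else:
            probs = forward_mlm(model, ex.input_matrix[None])
            p = probs[0, ex.selected_positions]
        w_loss = soft_cross_entropy(p, ex.targets)
        per_window.append(w_loss)
        total += w_loss * len(selected)
        n += len(selected)
    if n == 0:
        raise ValueError("evaluation produced no selected positions")
    mean_loss = total / n
    return EvalReport(mean_loss=mean_loss,
                      perplexity=perplexity_from_loss(mean_loss),
                      n_positions=n, per_window_loss=per_window)


@dataclass
class RecoveryReport:
    """KL divergences between temperature-scaled planted distributions
    and model predictions at probed loci; ``predictions`` holds the
    renormalized per-locus nucleotide distributions in probe order."""

    per_locus: list[tuple[str, int, float]]
    mean_kl: float
    max_kl: float
    predictions: list[np.ndarray] = field(default_factory=list)


def kl_divergence(q: np.ndarray, p: np.ndarray,
                  floor: float = LOG_FLOOR) -> float:
    """KL(q || p) over q's support."""
    q = np.asarray(q, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    support = q > 0
    return float((q[support] * np.log(q[support]
                                      / np.maximum(p[support], floor))).sum())


def allele_frequency_recovery(model, pg: ProbabilisticGenome,
                              truth: list[tuple[str, int, np.ndarray]],
                              tau: float = 0.7,
                              window_length: int = 128) -> RecoveryReport:
    """Probe each planted locus under [MASK] and score the prediction.

    For each (contig, 0-based position, planted A/C/G/T distribution),
    the locus's column in a window centered on it is replaced by a
    one-hot [MASK]; the model's predicted distribution, renormalized over
    the nucleotide rows, is compared with the temperature-scaled planted
    distribution by KL(q' || p_hat). ``model`` may be a
    :class:`ProbEncoder` or a callable (matrix, column) -> 9-distribution.
    """
    per_locus: list[tuple[str, int, float]] = []
    predictions: list[np.ndarray] = []
    for contig, pos0, dist in truth:
        if not pg.is_variant(contig, pos0):
            raise KeyError(f"probe locus {contig}:{pos0} is not a stored "
                           "variant")
        stream = pg.stream(contig)
        stream_pos = int(np.searchsorted(stream.coords, pos0))
        if stream.coords[stream_pos] != pos0:
            raise KeyError(f"{contig}:{pos0} not on a reference segment")
        n = len(stream.seq)
        if n < window_length:
            raise ValueError(f"contig {contig} shorter than probe window")
        start = min(max(stream_pos - window_length // 2, 0),
                    n - window_length)
        window = encode_window(pg, contig, start, window_length)
        (cols,) = np.nonzero(window.coords == pos0)
        col = int(cols[0])
        probe = window.matrix.copy()
        probe[:, col] = 0.0
        probe[MASK, col] = 1.0
        if callable(model) and not isinstance(model, ProbEncoder):
            p9 = np.asarray(model(probe, col), dtype=np.float64)
        else:
            p9 = forward_mlm(model, probe[None])[0, col]
        p_nuc = p9[NUC_SLICE]
        p_nuc = p_nuc / p_nuc.sum()
        q_prime = temperature_scale(np.asarray(dist, dtype=np.float64), tau)
        per_locus.append((contig, pos0, kl_divergence(q_prime, p_nuc)))
        predictions.append(p_nuc)
    kls = [k for _, _, k in per_locus]
    return RecoveryReport(per_locus=per_locus,
                          mean_kl=float(np.mean(kls)),
                          max_kl=float(np.max(kls)),
                          predictions=predictions)
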