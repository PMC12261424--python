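"""Variant-effect embeddings and a minimal fine-tuning harness.

For variant-effect analysis a checkpoint is probed, not retrained: the
reference and alternate sequences (identical except at the variant) are
each run through the encoder, final-layer states are mean-pooled over a
window centered on the variant (1536 bp by default, clipped at sequence
ends), and the two pooled vectors are concatenated reference-first. The
fine-tuning harness trains a classification head with linear warmup,
periodic validation, and early stopping on the Matthews correlation
coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model.encoder import ProbEncoder
from .model.layers import Linear, softmax
from .model.optim import AdamW
from .windows import EncodedWindow, encode_sequence

log = logging.getLogger(__name__)


# -- embeddings ----------------------------------------------------------


@dataclass
class VariantPairEmbedding:
    """Mean-pooled encoder states around a variant, reference first."""

    ref_embedding: np.ndarray
    alt_embedding: np.ndarray
    concatenated: np.ndarray
    pool_bp: int


def pooled_indices(seq_len: int, variant_offset: int,
                   pool_bp: int) -> np.ndarray:
    """0-based sequence offsets pooled for a variant at
    ``variant_offset``: a ``pool_bp`` window centered on the variant,
    clipped at the sequence ends."""
    lo = max(0, variant_offset - pool_bp // 2)
    hi = min(seq_len, variant_offset - pool_bp // 2 + pool_bp)
    return np.arange(lo, hi)


def _pooled_state(model: ProbEncoder, sequence: str,
                  variant_offset: int, pool_bp: int) -> np.ndarray:
    matrix = encode_sequence(sequence)
    model.forward(matrix[None], l_test=matrix.shape[1])
    hidden = model.hidden_states()[0]          # (L, d), L = len + 2
    idx = pooled_indices(len(sequence), variant_offset, pool_bp)
    return hidden[idx + 1].mean(axis=0)        # +1 skips the [CLS] column


def variant_embedding_pair(model: ProbEncoder, ref_sequence: str,
                           alt_sequence: str, variant_offset: int,
                           pool_bp: int = 1536) -> VariantPairEmbedding:
    """Embed a ref/alt sequence pair for variant-effect analysis.

    The sequences must be the same length and differ at exactly
    ``variant_offset``. Sequences longer than the pretraining context are
    handled by the encoder's dynamic NTK scaling.
    """
    if len(ref_sequence) != len(alt_sequence):
        raise ValueError("ref and alt sequences must have equal length")
    diffs = [i for i, (a, b) in enumerate(zip(ref_sequence, alt_sequence))
             if a != b]
    if diffs != [variant_offset]:
        raise ValueError(
            f"sequences differ at {diffs}, expected exactly "
            f"[{variant_offset}]")
    ref_emb = _pooled_state(model, ref_sequence, variant_offset, pool_bp)
    alt_emb = _pooled_state(model, alt_sequence, variant_offset, pool_bp)
    return VariantPairEmbedding(
        ref_embedding=ref_emb, alt_embedding=alt_emb,
        concatenated=np.concatenate([ref_emb, alt_emb]), pool_bp=pool_bp)


# -- metrics -------------------------------------------------------------


def confusion_table(y_true: np.ndarray, y_pred: np.ndarray,
                    n_classes: int | None = None) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    table = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(table, (y_true, y_pred), 1)
    return table


def mcc(confusion: np.ndarray) -> float:
    """Matthews correlation coefficient from a square confusion table
    (rows = truth, columns = prediction), via the multi-class
    generalization; returns 0 when a marginal degenerates."""
    cmat = np.asarray(confusion, dtype=np.float64)
    if cmat.size == 0:
        raise ValueError("empty confusion table")
    if cmat.ndim != 2 or cmat.shape[0] != cmat.shape[1] or cmat.shape[0] < 2:
        raise ValueError("confusion table must be square with >= 2 classes")
    t = cmat.sum(axis=1)   # truth marginals
    p = cmat.sum(axis=0)   # prediction marginals
    c = np.trace(cmat)
    s = cmat.sum()
    num = c * s - p @ t
    den_sq = (s * s - p @ p) * (s * s - t @ t)
    if den_sq <= 0:
        return 0.0
    return float(num / np.sqrt(den_sq))


def should_stop(metric_trace: list[float], patience: int) -> bool:
    """Early-stopping rule: stop once the latest ``patience`` checks all
    failed to improve on the best value seen before them."""
    if len(metric_trace) <= patience:
        return False
    best = -np.inf
    since_best = 0
    for m in metric_trace:
        if m > best:
            best = m
            since_best = 0
        else:
            since_best += 1
    return since_best >= patience


# -- fine-tuning ---------------------------------------------------------


@dataclass
class FinetuneConfig:
    """Head-training schedule; the step counts and patience are the
    standard fine-tuning protocol. ``lr`` is the standard (full or
    head-only) fine-tuning rate; when ``use_lora`` is set the encoder's
    attention projections are wrapped with rank-``lora_rank`` adapters
    (update scaled by alpha/rank) and trained at ``lora_lr`` instead."""

    steps: int = 1000
    warmup_steps: int = 50
    batch_size: int = 32
    lr: float = 3e-5
    val_every: int = 200
    patience: int = 5
    seed: int = 0
    train_backbone: bool = False
    use_lora: bool = False
    lora_rank: int = 8
    lora_alpha: float = 16.0
    lora_lr: float = 1e-4


@dataclass
class FinetuneResult:
    head: Linear
    trace: list[tuple[int, float]] = field(default_factory=list)
    best_mcc: float = -1.0
    best_step: int = 0


def _to_matrix(x) -> np.ndarray:
    if isinstance(x, EncodedWindow):
        return x.matrix
    if isinstance(x, str):
        return encode_sequence(x)
    return np.asarray(x, dtype=np.float64)


def _pool_embedding(model: ProbEncoder, matrix: np.ndarray) -> np.ndarray:
    model.forward(matrix[None], l_test=matrix.shape[1])
    hidden = model.hidden_states()[0]
    return hidden[1:-1].mean(axis=0)   # genomic columns only


def finetune_classifier(model: ProbEncoder, train_data, val_data,
                        config: FinetuneConfig | None = None
                        ) -> FinetuneResult:
    """Train a linear classification head on mean-pooled encoder states.

    ``train_data``/``val_data`` are sequences of (window, label) where a
    window is an :class:`EncodedWindow`, an A/C/G/T string, or a 9xL
    matrix. Validation runs every ``val_every`` steps; training stops
    early when the validation MCC fails to improve for ``patience``
    consecutive checks, and the best head (by validation MCC) is
    returned. The backbone stays frozen by default.
    """
    config = config or FinetuneConfig()
    if config.use_lora:
        from .model.lora import LoraSpec, lora_wrap
        lora_wrap(model, LoraSpec(rank=config.lora_rank,
                                  alpha=config.lora_alpha),
                  seed=config.seed)
    through_backbone = config.train_backbone or config.use_lora
    base_lr = config.lora_lr if config.use_lora else config.lr
    labels = np.asarray([y for _, y in train_data], dtype=np.int64)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training set has a single class")
    n_classes = int(labels.max()) + 1
    rng = np.random.default_rng(config.seed)

    matrices = [_to_matrix(w) for w, _ in train_data]
    val_matrices = [_to_matrix(w) for w, _ in val_data]
    yv = np.asarray([y for _, y in val_data], dtype=np.int64)

    X = Xv = None
    if not through_backbone:
        # frozen backbone: embed once, then the head trains on fixed vectors
        X = np.stack([_pool_embedding(model, m) for m in matrices])
        Xv = np.stack([_pool_embedding(model, m) for m in val_matrices])
    else:
        lengths = {m.shape[1] for m in matrices + val_matrices}
        if len(lengths) != 1:
            raise ValueError("backbone fine-tuning requires equal-length "
                             "windows")

    d = model.config.hidden_size
    head = Linear(d, n_classes, rng, init_std=0.02, name="classifier")
    params = head.parameters()
    if through_backbone:
        params = model.parameters() + params
    optimizer = AdamW(params, lr=base_lr, weight_decay=0.01)
    trace: list[tuple[int, float]] = []
    metric_values: list[float] = []
    best = FinetuneResult(head=head)
    best_weights = (head.W.value.copy(), head.b.value.copy())

    def _val_predictions() -> np.ndarray:
        if not through_backbone:
            return head.forward(Xv).argmax(axis=-1)
        emb = np.stack([_pool_embedding(model, m) for m in val_matrices])
        return head.forward(emb).argmax(axis=-1)

    for step in range(1, config.steps + 1):
        idx = rng.integers(0, len(matrices),
                           size=min(config.batch_size, len(matrices)))
        y = labels[idx]
        optimizer.zero_grad()
        if not through_backbone:
            logits = head.forward(X[idx])
            probs = softmax(logits)
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(y)), y] = 1.0
            head.backward((probs - onehot) / len(y))
        else:
            batch = np.stack([matrices[i] for i in idx])
            mlm_logits = model.forward(batch, l_test=batch.shape[2])
            hidden = model.hidden_states()          # (B, L, d)
            pooled = hidden[:, 1:-1].mean(axis=1)
            logits = head.forward(pooled)
            probs = softmax(logits)
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(y)), y] = 1.0
            dpooled = head.backward((probs - onehot) / len(y))
            dhidden = np.zeros_like(hidden)
            dhidden[:, 1:-1] = dpooled[:, None, :] / (hidden.shape[1] - 2)
            model.backward(np.zeros_like(mlm_logits), dhidden=dhidden)
        scale = min(1.0, step / config.warmup_steps)
        optimizer.lr = base_lr * scale
        optimizer.step()

        if step % config.val_every == 0 or step == config.steps:
            m = mcc(confusion_table(yv, _val_predictions(), n_classes))
            trace.append((step, m))
            metric_values.append(m)
            if m > best.best_mcc:
                best.best_mcc = m
                best.best_step = step
                best_weights = (head.W.value.copy(), head.b.value.copy())
            if should_stop(metric_values, config.patience):
                log.info("early stop at step %d (best MCC %.3f at %d)",
                         step, best.best_mcc, best.best_step)
                break

    head.W.value[...] = best_weights[0]
    head.b.value[...] = best_weights[1]
    best.head = head
    best.trace = trace
    return best


def finetune_multi_seed(model: ProbEncoder, train_data, val_data,
                        config: FinetuneConfig | None = None,
                        seeds: tuple[int, ...] = (0, 1, 2)
                        ) -> tuple[float, list[FinetuneResult]]:
    """Run fine-tuning once per seed and report the mean best MCC, the
    conventional multi-seed protocol."""
    config = config or FinetuneConfig()
    results = []
    for seed in seeds:
        cfg = FinetuneConfig(**{**config.__dict__, "seed": seed})
        results.append(finetune_classifier(model, train_data, val_data, cfg))
    return float(np.mean([r.best_mcc for r in results])), results
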