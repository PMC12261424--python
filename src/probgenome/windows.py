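"""Encode genome windows as 9xL column-stochastic matrices.

A window is addressed by (contig, start, length) where ``start`` is an
offset into the contig's concatenated N-free segment stream; this makes
every in-range start valid and mirrors how training windows are sampled
from the [SEP]-joined segment stream. The encoded layout is
[CLS] + genomic columns + [SEP], with an extra internal [SEP] column
wherever the window crosses a segment boundary (i.e. an excised N run).
Original contig coordinates are kept per column; special columns carry a
sentinel of -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidWindowError
from .genome import ProbabilisticGenome
from .vocab import BASE_TO_ROW, CLS, NUC_SLICE, SEP, VOCAB_SIZE

COORD_SENTINEL = -1


@dataclass
class EncodedWindow:
    """Dense 9xL probability matrix for one training window."""

    matrix: np.ndarray     # (9, L), columns sum to 1
    is_snv: np.ndarray     # (L,) bool, True at stored variant loci
    is_special: np.ndarray  # (L,) bool, True at [CLS]/[SEP] columns
    coords: np.ndarray     # (L,) original contig coordinates, -1 at specials
    contig: str

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_effective(self) -> int:
        """Number of genomic (maskable) columns."""
        return int((~self.is_special).sum())


def encode_window(pg: ProbabilisticGenome, contig: str,
                  start: int, length: int = 510) -> EncodedWindow:
    """Encode ``length`` stream positions of ``contig`` starting at
    ``start`` into an :class:`EncodedWindow`.

    Output has ``length + 2 + (#internal segment boundaries)`` columns.
    Genomic columns carry the locus's allele distribution in the
    nucleotide rows; stored variant loci are flagged ``is_snv``.
    """
    if contig not in pg.reference.contigs:
        raise InvalidWindowError(f"unknown contig {contig!r}")
    stream = pg.stream(contig)
    n = len(stream.seq)
    if length < 1:
        raise InvalidWindowError("window length must be >= 1")
    if start < 0 or start + length > n:
        raise InvalidWindowError(
            f"window [{start},{start + length}) outside stream of {contig} "
            f"(length {n})")

    # internal boundaries strictly inside (start, start+length)
    b_lo = np.searchsorted(stream.boundaries, start, side="right")
    b_hi = np.searchsorted(stream.boundaries, start + length, side="left")
    internal = stream.boundaries[b_lo:b_hi]

    L = length + 2 + len(internal)
    matrix = np.zeros((VOCAB_SIZE, L))
    is_snv = np.zeros(L, dtype=bool)
    is_special = np.zeros(L, dtype=bool)
    coords = np.full(L, COORD_SENTINEL, dtype=np.int64)

    matrix[CLS, 0] = 1.0
    matrix[SEP, L - 1] = 1.0
    is_special[0] = is_special[L - 1] = True

    # variant loci inside the window, as offsets into the stream slice
    v_lo = np.searchsorted(stream.var_stream_pos, start)
    v_hi = np.searchsorted(stream.var_stream_pos, start + length)
    var_at = {int(p): stream.var_probs[i]
              for i, p in zip(range(v_lo, v_hi),
                              stream.var_stream_pos[v_lo:v_hi])}

    col = 1
    boundary_iter = iter(internal)
    next_boundary = next(boundary_iter, None)
    for s in range(start, start + length):
        if next_boundary is not None and s == next_boundary:
            matrix[SEP, col] = 1.0
            is_special[col] = True
            col += 1
            next_boundary = next(boundary_iter, None)
        probs = var_at.get(s)
        if probs is not None:
            matrix[NUC_SLICE, col] = probs
            is_snv[col] = True
        else:
            matrix[BASE_TO_ROW[stream.seq[s]], col] = 1.0
        coords[col] = stream.coords[s]
        col += 1

    return EncodedWindow(matrix=matrix, is_snv=is_snv,
                         is_special=is_special, coords=coords, contig=contig)


def encode_sequence(sequence: str, add_specials: bool = True) -> np.ndarray:
    """One-hot 9xL matrix for a plain A/C/G/T string (deterministic
    encoding used for downstream fine-tuning inputs)."""
    seq = sequence.upper()
    L = len(seq) + (2 if add_specials else 0)
    matrix = np.zeros((VOCAB_SIZE, L))
    off = 1 if add_specials else 0
    if add_specials:
        matrix[CLS, 0] = 1.0
        matrix[SEP, L - 1] = 1.0
    for i, base in enumerate(seq):
        row = BASE_TO_ROW.get(base)
        if row is None:
            raise ValueError(f"ambiguous base {base!r} at offset {i}")
        matrix[row, off + i] = 1.0
    return matrix
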