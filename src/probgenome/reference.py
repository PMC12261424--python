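"""Reference genome backbone: FASTA loading and ambiguity-free segments.

A contig is stored as an ordered list of segments of unambiguous sequence.
Runs of N (or any other non-ACGT code) split a contig; the original contig
coordinates of every segment are preserved in its start offset, so variant
records can be anchored without any liftover. Downstream, windows are
sampled from the concatenation of a contig's segments, with segment
boundaries rendered as [SEP] columns.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

_ACGT_RUN = re.compile(r"[ACGT]+")


@dataclass(frozen=True)
class Segment:
    """A maximal run of unambiguous sequence within a contig.

    ``start`` is the 0-based offset of the first base in original contig
    coordinates; ``seq`` is uppercase and contains only A/C/G/T.
    """

    start: int
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


def split_segments(sequence: str) -> list[Segment]:
    """Split a raw contig sequence at every run of ambiguous characters.

    Case is folded to uppercase first; anything outside A/C/G/T acts as a
    separator and is dropped.
    """
    upper = sequence.upper()
    return [Segment(m.start(), m.group()) for m in _ACGT_RUN.finditer(upper)]


@dataclass
class ReferenceGenome:
    """Ambiguity-free reference backbone, one segment list per contig."""

    contigs: dict[str, list[Segment]] = field(default_factory=dict)

    def contig_names(self) -> list[str]:
        return list(self.contigs)

    def stream_length(self, contig: str) -> int:
        """Total unambiguous bases in ``contig`` (length of its
        concatenated segment stream)."""
        return sum(len(s) for s in self.contigs[contig])

    def total_bp(self) -> int:
        return sum(self.stream_length(c) for c in self.contigs)

    def segment_at(self, contig: str, position: int) -> Segment | None:
        """Return the segment covering 0-based contig ``position``,
        or None if the position was removed as ambiguous."""
        for seg in self.contigs.get(contig, ()):
            if seg.start <= position < seg.end:
                return seg
        return None

    def base_at(self, contig: str, position: int) -> str | None:
        seg = self.segment_at(contig, position)
        if seg is None:
            return None
        return seg.seq[position - seg.start]


def load_reference(fasta_path: str | Path,
                   contig_filter: list[str] | None = None) -> ReferenceGenome:
    """Load a FASTA file into a :class:`ReferenceGenome`.

    Each contig is split at runs of N or any other ambiguity code into
    segments of pure A/C/G/T, with original coordinates preserved.

    Parameters
    ----------
    fasta_path:
        Plain or gzip-compressed FASTA.
    contig_filter:
        Optional list of contig names to keep; every listed name must be
        present in the file.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    contigs: dict[str, list[Segment]] = {}
    wanted = set(contig_filter) if contig_filter is not None else None
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if wanted is not None and record.id not in wanted:
                continue
            contigs[record.id] = split_segments(str(record.seq))
    if wanted is not None:
        missing = wanted - contigs.keys()
        if missing:
            raise KeyError(
                f"contigs requested but absent from {path}: {sorted(missing)}")
    if not contigs:
        raise ValueError(f"no contigs read from {path}")
    return ReferenceGenome(contigs)
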