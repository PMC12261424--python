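"""Probabilistic genome: a reference backbone plus sparse allele distributions.

Each stored locus maps to a probability distribution over A/C/G/T derived
from population allele frequencies or alignment-column counts. Loci
without observed variation are implicit: reconstructing their column
yields the reference base with probability exactly 1. The sparse layout
matters because within-species data is overwhelmingly invariant (well
under 1% of positions), so a dense 4xL matrix would be nearly all one-hots.

Internally coordinates are 0-based half-open. VCF and the MSA count table
are 1-based; the conversion happens exactly once, in the builders here.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .exceptions import CoordinateMismatchError, FormatVersionError
from .reference import ReferenceGenome, Segment
from .variants import VariantRecord
from .vocab import BASE_INDEX

log = logging.getLogger(__name__)

_FORMAT_NAME = "probgenome"
_FORMAT_VERSION = 1

PROVENANCES = ("population_vcf", "msa", "reference_only")


def allele_distribution(probs: Iterable[float]) -> np.ndarray:
    """Validate and return a 4-vector distribution over A,C,G,T."""
    p = np.asarray(list(probs), dtype=np.float64)
    if p.shape != (4,):
        raise ValueError("allele distribution must have 4 entries (A,C,G,T)")
    if np.any(p < 0):
        raise ValueError("allele distribution has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele distribution sums to {p.sum()}, not 1")
    return p


@dataclass
class _ContigStream:
    """Concatenated N-free view of one contig, cached for window encoding."""

    seq: str                 # all segments joined
    coords: np.ndarray       # stream index -> original contig coordinate
    boundaries: np.ndarray   # stream indices where a new segment begins (excl. 0)
    var_stream_pos: np.ndarray  # sorted stream indices of stored variant loci
    var_probs: np.ndarray       # (k, 4) rows aligned with var_stream_pos


@dataclass
class DatasetStats:
    """Corpus-level statistics over a probabilistic genome."""

    total_bp: int
    num_snv_loci: int
    snv_fraction: float
    num_windows: int
    windows_with_snv_fraction: float

    def to_tsv(self) -> str:
        rows = [
            ("total_bp", self.total_bp),
            ("num_snv_loci", self.num_snv_loci),
            ("snv_fraction", f"{self.snv_fraction:.6f}"),
            ("num_windows", self.num_windows),
            ("windows_with_snv_fraction", f"{self.windows_with_snv_fraction:.6f}"),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


class ProbabilisticGenome:
    """Reference backbone plus a sparse map of variable loci.

    Parameters
    ----------
    reference:
        The N-free segmented backbone.
    variant_map:
        ``(contig, 0-based position) -> 4-vector over A,C,G,T``. Only loci
        with at least two nonzero entries belong here; deterministic loci
        are implicit.
    min_af_threshold:
        The allele-frequency floor that was applied when building.
    provenance:
        One of ``population_vcf``, ``msa``, ``reference_only``.
    """

    def __init__(self,
                 reference: ReferenceGenome,
                 variant_map: dict[tuple[str, int], np.ndarray] | None = None,
                 min_af_threshold: float = 0.0,
                 provenance: str = "reference_only") -> None:
        if provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance: {provenance}")
        self.reference = reference
        self.variant_map: dict[tuple[str, int], np.ndarray] = {}
        self.min_af_threshold = float(min_af_threshold)
        self.provenance = provenance
        self._streams: dict[str, _ContigStream] = {}
        if variant_map:
            for key, probs in variant_map.items():
                self.variant_map[key] = allele_distribution(probs)

    # -- queries ---------------------------------------------------------

    def num_variant_loci(self) -> int:
        return len(self.variant_map)

    def distribution_at(self, contig: str, position: int) -> np.ndarray:
        """Dense A/C/G/T column at a 0-based position (implicit one-hot
        at unstored loci)."""
        stored = self.variant_map.get((contig, position))
        if stored is not None:
            return stored.copy()
        base = self.reference.base_at(contig, position)
        if base is None:
            raise KeyError(f"{contig}:{position} is not on a reference segment")
        col = np.zeros(4)
        col[BASE_INDEX[base]] = 1.0
        return col

    def is_variant(self, contig: str, position: int) -> bool:
        return (contig, position) in self.variant_map

    # -- concatenated stream view ---------------------------------------

    def stream(self, contig: str) -> _ContigStream:
        """Cached concatenated N-free view of ``contig`` (built lazily)."""
        cached = self._streams.get(contig)
        if cached is not None:
            return cached
        segments = self.reference.contigs[contig]
        parts: list[str] = []
        coords: list[np.ndarray] = []
        boundaries: list[int] = []
        offset = 0
        for seg in segments:
            if offset > 0:
                boundaries.append(offset)
            parts.append(seg.seq)
            coords.append(np.arange(seg.start, seg.end, dtype=np.int64))
            offset += len(seg)
        seq = "".join(parts)
        coord_arr = (np.concatenate(coords) if coords
                     else np.empty(0, dtype=np.int64))
        # map stored variant loci into stream coordinates
        pairs = [(pos, key) for key in self.variant_map
                 if key[0] == contig for pos in [key[1]]]
        var_stream, var_rows = [], []
        if pairs:
            coord_to_stream = {int(c): i for i, c in enumerate(coord_arr)}
            for pos, key in pairs:
                idx = coord_to_stream.get(pos)
                if idx is not None:
                    var_stream.append(idx)
                    var_rows.append(self.variant_map[key])
        order = np.argsort(var_stream) if var_stream else []
        stream = _ContigStream(
            seq=seq,
            coords=coord_arr,
            boundaries=np.asarray(boundaries, dtype=np.int64),
            var_stream_pos=np.asarray(var_stream, dtype=np.int64)[order]
            if len(var_stream) else np.empty(0, dtype=np.int64),
            var_probs=np.asarray(var_rows, dtype=np.float64)[order]
            if len(var_rows) else np.empty((0, 4), dtype=np.float64),
        )
        self._streams[contig] = stream
        return stream

    def _invalidate_streams(self) -> None:
        self._streams.clear()


# -- builders ------------------------------------------------------------


def _locate(reference: ReferenceGenome, contig: str, pos0: int) -> Segment | None:
    if contig not in reference.contigs:
        return None
    segs = reference.contigs[contig]
    starts = [s.start for s in segs]
    i = bisect_right(starts, pos0) - 1
    if i >= 0 and segs[i].start <= pos0 < segs[i].end:
        return segs[i]
    return None


def build_probabilistic_genome(
    reference: ReferenceGenome,
    variants: Iterable[VariantRecord],
    min_af: float = 0.02,
) -> ProbabilisticGenome:
    """Fold SNV records into a sparse probabilistic genome.

    Alt alleles below ``min_af`` are discarded and their probability mass
    reassigned to the reference allele, so every stored column sums to 1
    exactly; loci where no alt survives are left implicit. VCF's 1-based
    positions are converted to 0-based here (the single conversion point).

    Raises
    ------
    CoordinateMismatchError
        If a record's reference allele disagrees with the backbone base,
        which indicates a coordinate or assembly mismatch.
    """
    if not 0.0 <= min_af <= 1.0:
        raise ValueError(f"min_af must be in [0,1], got {min_af}")
    variant_map: dict[tuple[str, int], np.ndarray] = {}
    n_off_segment = 0
    for rec in variants:
        pos0 = rec.position - 1
        seg = _locate(reference, rec.contig, pos0)
        if seg is None:
            n_off_segment += 1
            continue
        base = seg.seq[pos0 - seg.start]
        if base != rec.ref_allele:
            raise CoordinateMismatchError(
                f"{rec.contig}:{rec.position}: VCF ref {rec.ref_allele!r} "
                f"but reference genome has {base!r}")
        kept = [(a, f) for a, f in zip(rec.alt_alleles, rec.alt_frequencies)
                if f >= min_af and a != rec.ref_allele]
        if not kept:
            continue
        col = np.zeros(4)
        for alt, freq in kept:
            col[BASE_INDEX[alt]] += freq
        col[BASE_INDEX[base]] = 1.0 - col.sum()
        variant_map[(rec.contig, pos0)] = col
    if n_off_segment:
        log.warning("build_probabilistic_genome: skipped %d variants on "
                    "positions removed as ambiguous or off-contig", n_off_segment)
    return ProbabilisticGenome(reference, variant_map,
                               min_af_threshold=min_af,
                               provenance="population_vcf")


MSA_TABLE_COLUMNS = ["contig", "position", "count_A", "count_C",
                     "count_G", "count_T", "count_gap"]


def read_msa_counts(path: str | Path) -> pd.DataFrame:
    """Read the headered tab-separated alignment-column count table.

    Columns: contig, position (1-based), count_A, count_C, count_G,
    count_T, count_gap. Gap counts cover alignment gaps and ambiguous
    characters; they are excluded from denominators downstream.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(MSA_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"MSA count table missing columns: {sorted(missing)}")
    return df


def build_from_msa(
    reference: ReferenceGenome,
    column_counts: pd.DataFrame | str | Path,
    min_af: float = 0.0,
) -> ProbabilisticGenome:
    """Build a probabilistic genome from alignment-column base counts.

    Each position's distribution is base counts divided by the total
    non-gap count; columns that reduce to the reference one-hot (including
    zero-usable-count columns, which fall back to the reference) are left
    implicit. No frequency threshold is applied by default; pass
    ``min_af`` to drop low-frequency non-reference mass onto the
    reference allele as in the population route.
    """
    if isinstance(column_counts, (str, Path)):
        column_counts = read_msa_counts(column_counts)
    variant_map: dict[tuple[str, int], np.ndarray] = {}
    n_off_segment = n_empty = 0
    for row in column_counts.itertuples(index=False):
        contig = str(row.contig)
        pos0 = int(row.position) - 1
        seg = _locate(reference, contig, pos0)
        if seg is None:
            n_off_segment += 1
            continue
        base = seg.seq[pos0 - seg.start]
        counts = np.array([row.count_A, row.count_C, row.count_G, row.count_T],
                          dtype=np.float64)
        total = counts.sum()
        if total <= 0:
            n_empty += 1
            continue  # fall back to the implicit reference one-hot
        col = counts / total
        if min_af > 0.0:
            ref_idx = BASE_INDEX[base]
            drop = (col < min_af) & (np.arange(4) != ref_idx)
            col[ref_idx] += col[drop].sum()
            col[drop] = 0.0
        if col[BASE_INDEX[base]] >= 1.0 - 1e-12:
            continue
        variant_map[(contig, pos0)] = col
    if n_off_segment or n_empty:
        log.warning("build_from_msa: skipped %d off-segment and %d "
                    "zero-count columns", n_off_segment, n_empty)
    return ProbabilisticGenome(reference, variant_map,
                               min_af_threshold=min_af, provenance="msa")


def reference_only_genome(reference: ReferenceGenome) -> ProbabilisticGenome:
    """Deterministic baseline: every locus is a reference one-hot."""
    return ProbabilisticGenome(reference, {}, provenance="reference_only")


# -- persistence ---------------------------------------------------------


def save_genome(pg: ProbabilisticGenome, path: str | Path) -> None:
    """Write a versioned HDF5 container (segments + sparse variant table)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _FORMAT_NAME
        f.attrs["version"] = _FORMAT_VERSION
        f.attrs["provenance"] = pg.provenance
        f.attrs["min_af_threshold"] = pg.min_af_threshold
        names = list(pg.reference.contigs)
        f.attrs["contig_order"] = json.dumps(names)
        str_dt = h5py.string_dtype()
        for i, name in enumerate(names):
            grp = f.create_group(f"contig/{i}")
            grp.attrs["name"] = name
            segs = pg.reference.contigs[name]
            grp.create_dataset("starts",
                               data=np.array([s.start for s in segs],
                                             dtype=np.int64))
            grp.create_dataset("seqs", data=[s.seq for s in segs], dtype=str_dt)
            keys = sorted(p for c, p in pg.variant_map if c == name)
            grp.create_dataset("var_pos", data=np.array(keys, dtype=np.int64))
            probs = (np.stack([pg.variant_map[(name, p)] for p in keys])
                     if keys else np.empty((0, 4)))
            grp.create_dataset("var_probs", data=probs)


def load_genome(path: str | Path) -> ProbabilisticGenome:
    """Inverse of :func:`save_genome`; fails on unknown version tags."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != _FORMAT_NAME:
            raise FormatVersionError(f"{path} is not a probgenome container")
        version = int(f.attrs.get("version", -1))
        if version != _FORMAT_VERSION:
            raise FormatVersionError(
                f"unsupported container version {version} in {path}")
        names = json.loads(f.attrs["contig_order"])
        contigs: dict[str, list[Segment]] = {}
        variant_map: dict[tuple[str, int], np.ndarray] = {}
        for i, name in enumerate(names):
            grp = f[f"contig/{i}"]
            starts = grp["starts"][:]
            seqs = [s.decode() if isinstance(s, bytes) else s
                    for s in grp["seqs"][:]]
            contigs[name] = [Segment(int(st), sq)
                             for st, sq in zip(starts, seqs)]
            var_pos = grp["var_pos"][:]
            var_probs = grp["var_probs"][:]
            for p, row in zip(var_pos, var_probs):
                variant_map[(name, int(p))] = row
        return ProbabilisticGenome(
            ReferenceGenome(contigs), variant_map,
            min_af_threshold=float(f.attrs["min_af_threshold"]),
            provenance=str(f.attrs["provenance"]))


# -- statistics ----------------------------------------------------------


def dataset_statistics(pg: ProbabilisticGenome,
                       window_length: int = 510,
                       n_windows: int = 1000,
                       seed: int = 0) -> DatasetStats:
    """Sample windows uniformly and report corpus statistics.

    Reports total unambiguous bases, the number and fraction of variant
    loci, and the fraction of ``n_windows`` uniformly sampled windows
    (over the concatenated segment streams of all contigs) that contain
    at least one variant locus.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    total_bp = pg.reference.total_bp()
    num_snv = pg.num_variant_loci()
    contigs = [c for c in pg.reference.contigs
               if pg.reference.stream_length(c) >= window_length]
    if not contigs:
        raise ValueError(
            f"no contig has >= {window_length} unambiguous bases")
    rng = np.random.default_rng(seed)
    starts_per_contig = np.array(
        [pg.reference.stream_length(c) - window_length + 1 for c in contigs],
        dtype=np.float64)
    probs = starts_per_contig / starts_per_contig.sum()
    hits = 0
    for _ in range(n_windows):
        ci = rng.choice(len(contigs), p=probs)
        contig = contigs[ci]
        start = int(rng.integers(0, int(starts_per_contig[ci])))
        stream = pg.stream(contig)
        lo = np.searchsorted(stream.var_stream_pos, start)
        hi = np.searchsorted(stream.var_stream_pos, start + window_length)
        if hi > lo:
            hits += 1
    return DatasetStats(
        total_bp=total_bp,
        num_snv_loci=num_snv,
        snv_fraction=num_snv / total_bp if total_bp else 0.0,
        num_windows=n_windows,
        windows_with_snv_fraction=hits / n_windows if n_windows else 0.0,
    )
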