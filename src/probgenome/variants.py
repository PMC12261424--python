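"""Streaming SNV extraction from VCF files.

Only single-nucleotide substitutions are used: indels, MNPs, symbolic and
structural alleles are skipped (with a counted warning) because the
probabilistic representation assigns one distribution per reference
position. Allele frequencies come from the INFO/AF field when present,
otherwise from genotype counting; the source is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from cyvcf2 import VCF

from .exceptions import UnusableRecordError

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass
class VariantRecord:
    """One biallelic or multiallelic SNV with per-alt allele frequencies.

    ``position`` is the 1-based coordinate exactly as read from the source
    file; conversion to the internal 0-based convention happens once, in
    :func:`probgenome.genome.build_probabilistic_genome`.
    """

    contig: str
    position: int
    ref_allele: str
    alt_alleles: list[str]
    alt_frequencies: list[float]

    def __post_init__(self) -> None:
        if self.ref_allele not in _BASES:
            raise ValueError(f"ref allele not a single base: {self.ref_allele!r}")
        for alt in self.alt_alleles:
            if alt not in _BASES:
                raise ValueError(f"alt allele not a single base: {alt!r}")
        if len(self.alt_alleles) != len(self.alt_frequencies):
            raise ValueError("alt_alleles and alt_frequencies length mismatch")
        total = 0.0
        for f in self.alt_frequencies:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency outside [0,1]: {f}")
            total += f
        if total > 1.0 + 1e-9:
            raise ValueError(f"alt frequencies sum to {total} > 1")


def _af_from_info(variant, n_alts: int):
    af = variant.INFO.get("AF")
    if af is None:
        return None
    if isinstance(af, (float, int)):
        values = [float(af)]
    else:
        values = [float(x) for x in af]
    if len(values) != n_alts:
        return None
    return values


def _af_from_genotypes(variant, n_alts: int):
    """Allele frequency as (alt allele count) / (total called alleles)."""
    counts = [0] * (n_alts + 1)
    total = 0
    genotypes = variant.genotypes
    if genotypes is None:
        return None
    for gt in genotypes:
        for allele in gt[:-1]:  # last slot is the phasing flag
            if allele is None or allele < 0:
                continue
            total += 1
            if allele <= n_alts:
                counts[allele] += 1
    if total == 0:
        return None
    return [counts[i + 1] / total for i in range(n_alts)]


def read_snv_frequencies(
    vcf_path: str | Path,
    contig_filter: list[str] | None = None,
    af_source: str = "auto",
    on_unusable: str = "skip",
) -> Iterator[VariantRecord]:
    """Yield a :class:`VariantRecord` per SNV in a VCF.

    Parameters
    ----------
    vcf_path:
        Plain or bgzipped VCF 4.x. A tabix index is used implicitly by
        htslib when present.
    contig_filter:
        Optional contig names to keep.
    af_source:
        ``"auto"`` (INFO/AF when present, else genotype counting),
        ``"info"`` (require INFO/AF), or ``"genotypes"`` (always count).
    on_unusable:
        ``"skip"`` (default) or ``"fail"`` for records with no usable
        frequency source.

    Multi-allelic records yield a single record carrying every single-base
    alt; non-SNV alleles are dropped, and records left with no usable alt
    are skipped. Skip totals are logged at the end of the stream.
    """
    if af_source not in ("auto", "info", "genotypes"):
        raise ValueError(f"unknown af_source: {af_source}")
    path = Path(vcf_path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    wanted = set(contig_filter) if contig_filter is not None else None
    n_non_snv = n_unusable = 0
    vcf = VCF(str(path))
    try:
        for variant in vcf:
            contig = variant.CHROM
            if wanted is not None and contig not in wanted:
                continue
            ref = variant.REF.upper()
            if len(ref) != 1 or ref not in _BASES:
                n_non_snv += 1
                continue
            alts = [a.upper() for a in variant.ALT]
            keep = [i for i, a in enumerate(alts)
                    if len(a) == 1 and a in _BASES]
            if len(keep) < len(alts):
                n_non_snv += 1
            if not keep:
                continue

            n_alts = len(alts)
            info_af = None if af_source == "genotypes" else _af_from_info(variant, n_alts)
            if info_af is not None:
                freqs = info_af
            elif af_source == "info":
                freqs = None
            else:
                freqs = _af_from_genotypes(variant, n_alts)
            if freqs is None:
                n_unusable += 1
                if on_unusable == "fail":
                    raise UnusableRecordError(
                        f"{contig}:{variant.POS} has neither AF nor genotypes")
                continue

            yield VariantRecord(
                contig=contig,
                position=variant.POS,
                ref_allele=ref,
                alt_alleles=[alts[i] for i in keep],
                alt_frequencies=[freqs[i] for i in keep],
            )
    finally:
        vcf.close()
    if n_non_snv or n_unusable:
        log.warning("read_snv_frequencies: skipped %d non-SNV allele sets, "
                    "%d records without usable frequencies", n_non_snv, n_unusable)
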