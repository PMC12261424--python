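"""Synthetic genomes, population VCFs, and alignment count tables.

The generators emulate the two data regimes the package targets:

* a within-species (1000 Genomes-like) regime — sparse biallelic SNVs at
  roughly 0.34% of positions, allele frequencies drawn from a skewed law
  bounded inside [0.02, 0.5] so every planted variant survives the 2%
  frequency filter, and diploid genotypes drawn under Hardy-Weinberg
  independence;
* a cross-species (multiple-alignment) regime — every species is an
  independently substituted copy of the reference, yielding dense
  variable columns (~70% of positions at the default 10 species).

Every generator is deterministic per seed, and each emits a
:class:`SimTruth` recording the exact planted distributions, the oracle
for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .reference import ReferenceGenome
from .vocab import BASES

_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Generator settings; defaults are the sparse population regime."""

    genome_length: int = 100_000
    n_contigs: int = 1
    contig_prefix: str = "chr"
    base_composition: tuple[float, float, float, float] = (0.25, 0.25,
                                                           0.25, 0.25)
    n_run_rate: float = 0.0          # per-bp probability an N run starts
    n_run_mean_length: float = 50.0  # geometric mean N-run length
    snv_density: float = 0.0034      # fraction of positions variant
    af_beta_a: float = 0.5           # skewed Beta(a,b) allele-frequency law
    af_beta_b: float = 3.0
    af_min: float = 0.02             # truncation bounds of the AF law
    af_max: float = 0.5
    multiallelic_prob: float = 0.0   # chance a variant site gets two alts
    n_samples: int = 32              # diploid samples in the emitted VCF
    n_species: int = 10              # rows in the emitted alignment
    substitution_prob: float = 0.113  # per-site, per-species (~70% variable)
    gap_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=np.float64)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1) > 1e-9:
            raise ValueError("base_composition must be 4 fractions summing to 1")
        for name in ("n_run_rate", "snv_density", "multiallelic_prob",
                     "substitution_prob", "gap_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.af_min < self.af_max <= 1.0:
            raise ValueError("need 0 <= af_min < af_max <= 1")


@dataclass
class SimTruth:
    """Planted variant loci (contig, 0-based position, A/C/G/T
    distribution) plus the seed and config that produced them."""

    loci: list[tuple[str, int, np.ndarray]]
    seed: int
    config: dict = field(default_factory=dict)

    def positions(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _ in self.loci}

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w") as f:
            f.write("contig\tposition_0based\tp_A\tp_C\tp_G\tp_T\n")
            for contig, pos, dist in self.loci:
                f.write(f"{contig}\t{pos}\t"
                        + "\t".join(f"{x:.10f}" for x in dist) + "\n")

    @classmethod
    def load_tsv(cls, path: str | Path, seed: int = -1) -> "SimTruth":
        df = pd.read_csv(path, sep="\t")
        loci = [(str(r.contig), int(r.position_0based),
                 np.array([r.p_A, r.p_C, r.p_G, r.p_T]))
                for r in df.itertuples(index=False)]
        return cls(loci=loci, seed=seed)


def _sim_rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def simulate_reference(config: SimConfig) -> dict[str, str]:
    """Draw contig sequences with the configured composition and
    planted N runs; byte-identical across calls with the same config."""
    if config.genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    rng = _sim_rng(config, 0)
    comp = np.asarray(config.base_composition)
    contigs: dict[str, str] = {}
    for ci in range(config.n_contigs):
        n = config.genome_length
        bases = rng.choice(4, size=n, p=comp)
        seq = _BASE_ARR[bases].copy()
        if config.n_run_rate > 0:
            starts = np.flatnonzero(rng.random(n) < config.n_run_rate)
            for s in starts:
                length = rng.geometric(1.0 / config.n_run_mean_length)
                seq[s:s + length] = b"N"
        contigs[f"{config.contig_prefix}{ci + 1}"] = (
            seq.tobytes().decode("ascii"))
    return contigs


def write_fasta(contigs: dict[str, str], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as f:
        for name, seq in contigs.items():
            f.write(f">{name}\n")
            for i in range(0, len(seq), width):
                f.write(seq[i:i + width] + "\n")


def _draw_af(rng: np.random.Generator, config: SimConfig,
             size: int) -> np.ndarray:
    """Skewed Beta(a,b) law truncated to [af_min, af_max] by inverse-CDF."""
    dist = stats.beta(config.af_beta_a, config.af_beta_b)
    lo, hi = dist.cdf(config.af_min), dist.cdf(config.af_max)
    return dist.ppf(rng.uniform(lo, hi, size=size))


def simulate_population_vcf(reference: ReferenceGenome, config: SimConfig,
                            vcf_path: str | Path) -> SimTruth:
    """Plant SNVs on the reference and emit a VCF 4.2 with AF INFO and
    Hardy-Weinberg diploid genotypes.

    Each unambiguous position independently becomes variant with
    probability ``snv_density`` (so the locus count is binomial). The
    written AF values are the exact planted frequencies; genotypes are
    drawn per chromosome copy at that frequency.
    """
    rng = _sim_rng(config, 1)
    loci: list[tuple[str, int, np.ndarray]] = []
    lines: list[str] = []
    header = ["##fileformat=VCFv4.2",
              "##source=probgenome-simulate"]
    contig_lengths = {
        name: (max(s.end for s in segs) if segs else 0)
        for name, segs in reference.contigs.items()}
    for name, length in contig_lengths.items():
        header.append(f"##contig=<ID={name},length={length}>")
    header.append('##INFO=<ID=AF,Number=A,Type=Float,'
                  'Description="Allele Frequency">')
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,'
                  'Description="Genotype">')
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(samples))

    for contig, segments in reference.contigs.items():
        for seg in segments:
            hits = np.flatnonzero(rng.random(len(seg)) < config.snv_density)
            for off in hits:
                pos0 = seg.start + int(off)
                ref_base = seg.seq[off]
                others = [b for b in BASES if b != ref_base]
                two_alts = rng.random() < config.multiallelic_prob
                if two_alts:
                    alts = list(rng.choice(others, size=2, replace=False))
                    total_af = float(_draw_af(rng, config, 1)[0])
                    freqs = [total_af / 2, total_af / 2]
                else:
                    alts = [str(rng.choice(others))]
                    freqs = [float(_draw_af(rng, config, 1)[0])]
                dist = np.zeros(4)
                for alt, f in zip(alts, freqs):
                    dist["ACGT".index(alt)] = f
                dist["ACGT".index(ref_base)] = 1.0 - sum(freqs)
                loci.append((contig, pos0, dist))
                # diploid genotypes: allele per chromosome copy, HW independence
                probs = np.array([1.0 - sum(freqs)] + freqs)
                gt = rng.choice(len(probs), p=probs,
                                size=(config.n_samples, 2))
                gt_strs = [f"{a}|{b}" for a, b in gt]
                af_str = ",".join(f"{f:.17g}" for f in freqs)
                lines.append(f"{contig}\t{pos0 + 1}\t.\t{ref_base}\t"
                             f"{','.join(alts)}\t.\tPASS\tAF={af_str}\tGT\t"
                             + "\t".join(gt_strs))
    with open(vcf_path, "w") as f:
        f.write("\n".join(header + lines) + "\n")
    return SimTruth(loci=loci, seed=config.seed, config=asdict(config))


def simulate_msa(reference: ReferenceGenome, config: SimConfig
                 ) -> tuple[pd.DataFrame, SimTruth]:
    """Emit per-position alignment base/gap counts over ``n_species``
    independently substituted copies of the reference.

    Every species substitutes each site with probability
    ``substitution_prob`` (uniformly to one of the three other bases) and
    gaps it with probability ``gap_prob`` (gaps are excluded from base
    counts). Returns the count table (one row per unambiguous position)
    and the realized column distributions of the variable columns.
    """
    if config.n_species < 2:
        raise ValueError("need at least 2 species")
    rng = _sim_rng(config, 2)
    rows = []
    loci: list[tuple[str, int, np.ndarray]] = []
    for contig, segments in reference.contigs.items():
        for seg in segments:
            n = len(seg)
            ref_idx = np.frombuffer(seg.seq.encode(), dtype="S1")
            ref_codes = np.searchsorted(_BASE_ARR, ref_idx)
            # (species, position) base codes after substitution
            codes = np.tile(ref_codes, (config.n_species, 1))
            sub = rng.random((config.n_species, n)) < config.substitution_prob
            shift = rng.integers(1, 4, size=(config.n_species, n))
            codes = np.where(sub, (codes + shift) % 4, codes)
            gaps = (rng.random((config.n_species, n)) < config.gap_prob
                    if config.gap_prob > 0
                    else np.zeros((config.n_species, n), dtype=bool))
            for off in range(n):
                col_codes = codes[:, off][~gaps[:, off]]
                counts = np.bincount(col_codes, minlength=4)
                gap_count = int(gaps[:, off].sum())
                pos0 = seg.start + off
                rows.append((contig, pos0 + 1, *counts.tolist(), gap_count))
                total = counts.sum()
                if total > 0:
                    dist = counts / total
                    if dist[ref_codes[off]] < 1.0:
                        loci.append((contig, pos0, dist))
    table = pd.DataFrame(rows, columns=["contig", "position", "count_A",
                                        "count_C", "count_G", "count_T",
                                        "count_gap"])
    truth = SimTruth(loci=loci, seed=config.seed, config=asdict(config))
    return table, truth


def save_sim_config(config: SimConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=2) + "\n")
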