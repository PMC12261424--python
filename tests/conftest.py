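"""Shared fixtures: tiny synthetic genomes built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from probgenome import (MaskingPolicy, ProbabilisticGenome, ReferenceGenome,
                        Segment, build_probabilistic_genome, load_reference,
                        read_snv_frequencies)
from probgenome.simulate import (SimConfig, simulate_population_vcf,
                                 simulate_reference, write_fasta)


@pytest.fixture
def toy_reference() -> ReferenceGenome:
    """Two contigs, one with an excised N run splitting it in two."""
    return ReferenceGenome({
        "chrA": [Segment(0, "ACGTACGTACGT"), Segment(16, "GGGTTTCCCAAA")],
        "chrB": [Segment(0, "ACGT" * 50)],
    })


@pytest.fixture
def toy_genome(toy_reference) -> ProbabilisticGenome:
    """Toy reference with a handful of hand-placed variant loci."""
    variant_map = {
        # reference bases: chrA:2 = G, chrA:17 = G, chrB:10 = G
        ("chrA", 2): np.array([0.0, 0.1, 0.9, 0.0]),
        ("chrA", 17): np.array([0.3, 0.0, 0.7, 0.0]),
        ("chrB", 10): np.array([0.0, 0.25, 0.6, 0.15]),
    }
    return ProbabilisticGenome(toy_reference, variant_map,
                               min_af_threshold=0.02,
                               provenance="population_vcf")


@pytest.fixture
def default_policy() -> MaskingPolicy:
    return MaskingPolicy()


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Small simulated population dataset: reference, VCF, truth, genome."""
    out = tmp_path_factory.mktemp("sim")
    cfg = SimConfig(genome_length=30_000, snv_density=0.002, seed=42,
                    n_run_rate=0.0003, n_samples=20)
    fasta = out / "ref.fa"
    write_fasta(simulate_reference(cfg), fasta)
    reference = load_reference(fasta)
    vcf = out / "variants.vcf"
    truth = simulate_population_vcf(reference, cfg, vcf)
    pg = build_probabilistic_genome(
        reference, read_snv_frequencies(vcf), min_af=0.02)
    return {"config": cfg, "fasta": fasta, "vcf": vcf, "truth": truth,
            "reference": reference, "genome": pg, "dir": out}
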