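"""Probabilistic-genome construction: the frequency filter, mass
conservation, the MSA route, persistence, and statistics."""

import numpy as np
import pytest

from probgenome import (VariantRecord, build_from_msa,
                        build_probabilistic_genome, dataset_statistics,
                        load_genome, reference_only_genome, save_genome)
from probgenome.exceptions import CoordinateMismatchError, FormatVersionError
from probgenome.genome import read_msa_counts
import pandas as pd


def _rec(contig, pos, ref, alts, freqs):
    return VariantRecord(contig=contig, position=pos, ref_allele=ref,
                         alt_alleles=list(alts), alt_frequencies=list(freqs))


class TestBuildFromVcf:
    def test_rare_alt_discarded_entirely(self, toy_reference):
        # chrA 1-based position 1 is 'A'
        pg = build_probabilistic_genome(
            toy_reference, [_rec("chrA", 1, "A", "G", [0.01])], min_af=0.02)
        assert pg.num_variant_loci() == 0
        assert pg.distribution_at("chrA", 0)[0] == 1.0  # implicit one-hot

    def test_common_alt_stored(self, toy_reference):
        pg = build_probabilistic_genome(
            toy_reference, [_rec("chrA", 1, "A", "G", [0.10])], min_af=0.02)
        np.testing.assert_allclose(pg.distribution_at("chrA", 0),
                                   [0.90, 0.0, 0.10, 0.0])

    def test_multiallelic_partial_filter_reassigns_to_ref(self,
                                                          toy_reference):
        pg = build_probabilistic_genome(
            toy_reference,
            [_rec("chrA", 1, "A", ["G", "T"], [0.05, 0.01])], min_af=0.02)
        np.testing.assert_allclose(pg.distribution_at("chrA", 0),
                                   [0.95, 0.0, 0.05, 0.0])

    def test_ref_mismatch_raises(self, toy_reference):
        with pytest.raises(CoordinateMismatchError):
            build_probabilistic_genome(
                toy_reference, [_rec("chrA", 1, "C", "G", [0.5])])

    def test_variant_on_removed_position_skipped(self, toy_reference):
        # chrA positions 12..15 (0-based) were excised; 1-based 13 is off
        pg = build_probabilistic_genome(
            toy_reference, [_rec("chrA", 13, "A", "G", [0.5])])
        assert pg.num_variant_loci() == 0

    def test_filter_monotonicity_and_extremes(self, toy_reference):
        recs = [_rec("chrB", i + 1, "ACGT"[i % 4], "ACGT"[(i + 1) % 4],
                     [0.01 + 0.02 * (i % 20)]) for i in range(40)]
        counts = []
        for min_af in (0.0, 0.05, 0.2, 0.5, 1.0):
            pg = build_probabilistic_genome(toy_reference, recs,
                                            min_af=min_af)
            counts.append(pg.num_variant_loci())
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 40   # min_af 0 keeps every observed alt
        assert counts[-1] == 0   # min_af 1 keeps none

    def test_mass_conservation_exact(self, toy_reference):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(50):
            ref = "ACGT"[i % 4]
            alt = "ACGT"[(i + 1 + int(rng.integers(0, 3))) % 4]
            if alt == ref:
                alt = "ACGT"[(i + 2) % 4]
            recs.append(_rec("chrB", i + 1, ref, alt,
                             [float(rng.uniform(0, 0.5))]))
        pg = build_probabilistic_genome(toy_reference, recs, min_af=0.1)
        for (contig, pos), dist in pg.variant_map.items():
            assert dist.sum() == pytest.approx(1.0, abs=1e-15)
            assert (dist > 0).sum() >= 2

    def test_dense_columns_sum_to_one(self, toy_genome):
        for pos in range(12):
            col = toy_genome.distribution_at("chrA", pos)
            assert col.sum() == pytest.approx(1.0, abs=1e-9)


class TestBrueForceOracle:
    """The builder must agree exactly with an independent line-by-line
    parse of the VCF text on a toy genome."""

    def test_matches_bruteforce_vcf_scan(self, sim_bundle):
        min_af = 0.02
        expected = {}
        for line in open(sim_bundle["vcf"]):
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, _, info = \
                line.rstrip("\n").split("\t")[:8]
            alts = alt.split(",")
            # VCF INFO Type=Float is 32-bit IEEE; parse accordingly
            afs = [float(np.float32(x)) for x in
                   info.split("AF=")[1].split(";")[0].split(",")]
            if len(ref) != 1 or any(len(a) != 1 for a in alts):
                continue
            col = np.zeros(4)
            kept = False
            for a, f in zip(alts, afs):
                if f >= min_af:
                    col["ACGT".index(a)] += f
                    kept = True
            if not kept:
                continue
            col["ACGT".index(ref)] = 1.0 - col.sum()
            expected[(chrom, int(pos) - 1)] = col
        pg = sim_bundle["genome"]
        assert set(pg.variant_map) == set(expected)
        for key, col in expected.items():
            np.testing.assert_allclose(pg.variant_map[key], col,
                                       atol=1e-12)


class TestBuildFromMsa:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["contig", "position", "count_A",
                                           "count_C", "count_G", "count_T",
                                           "count_gap"])

    def test_unanimous_ref_column_not_stored(self, toy_reference):
        pg = build_from_msa(toy_reference,
                            self._table([("chrA", 1, 10, 0, 0, 0, 0)]))
        assert pg.num_variant_loci() == 0

    def test_counts_normalized(self, toy_reference):
        pg = build_from_msa(toy_reference,
                            self._table([("chrA", 1, 7, 0, 3, 0, 0)]))
        np.testing.assert_allclose(pg.distribution_at("chrA", 0),
                                   [0.7, 0.0, 0.3, 0.0])

    def test_gaps_excluded_from_denominator(self, toy_reference):
        pg = build_from_msa(toy_reference,
                            self._table([("chrA", 1, 4, 0, 4, 0, 2)]))
        np.testing.assert_allclose(pg.distribution_at("chrA", 0),
                                   [0.5, 0.0, 0.5, 0.0])

    def test_zero_usable_counts_falls_back_to_reference(self,
                                                        toy_reference):
        pg = build_from_msa(toy_reference,
                            self._table([("chrA", 1, 0, 0, 0, 0, 10)]))
        assert pg.num_variant_loci() == 0
        assert pg.distribution_at("chrA", 0)[0] == 1.0

    def test_no_threshold_by_default_but_configurable(self, toy_reference):
        table = self._table([("chrA", 1, 99, 0, 1, 0, 0)])
        assert build_from_msa(toy_reference, table).num_variant_loci() == 1
        assert build_from_msa(toy_reference, table,
                              min_af=0.02).num_variant_loci() == 0

    def test_tsv_round_trip(self, toy_reference, tmp_path):
        table = self._table([("chrA", 1, 7, 0, 3, 0, 0),
                             ("chrA", 2, 0, 10, 0, 0, 0)])
        path = tmp_path / "counts.tsv"
        table.to_csv(path, sep="\t", index=False)
        assert read_msa_counts(path).equals(table)
        pg = build_from_msa(toy_reference, path)
        assert pg.num_variant_loci() == 1
        assert pg.provenance == "msa"


class TestPersistence:
    def test_round_trip_identity(self, sim_bundle, tmp_path):
        pg = sim_bundle["genome"]
        path = tmp_path / "g.h5"
        save_genome(pg, path)
        loaded = load_genome(path)
        assert loaded.provenance == pg.provenance
        assert loaded.min_af_threshold == pg.min_af_threshold
        assert loaded.reference.contigs == pg.reference.contigs
        assert set(loaded.variant_map) == set(pg.variant_map)
        for key in pg.variant_map:
            np.testing.assert_allclose(loaded.variant_map[key],
                                       pg.variant_map[key], atol=1e-12)

    def test_empty_variant_map_preserved(self, toy_reference, tmp_path):
        pg = reference_only_genome(toy_reference)
        path = tmp_path / "g.h5"
        save_genome(pg, path)
        loaded = load_genome(path)
        assert loaded.variant_map == {}
        assert loaded.provenance == "reference_only"

    def test_unknown_version_rejected(self, toy_reference, tmp_path):
        import h5py
        path = tmp_path / "g.h5"
        save_genome(reference_only_genome(toy_reference), path)
        with h5py.File(path, "a") as f:
            f.attrs["version"] = 999
        with pytest.raises(FormatVersionError):
            load_genome(path)

    def test_non_container_rejected(self, tmp_path):
        import h5py
        path = tmp_path / "other.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("x", data=[1, 2, 3])
        with pytest.raises(FormatVersionError):
            load_genome(path)


class TestDatasetStatistics:
    def test_reference_only_genome_all_zero(self, toy_reference):
        pg = reference_only_genome(toy_reference)
        stats = dataset_statistics(pg, window_length=10, n_windows=50,
                                   seed=1)
        assert stats.num_snv_loci == 0
        assert stats.snv_fraction == 0.0
        assert stats.windows_with_snv_fraction == 0.0
        assert stats.total_bp == toy_reference.total_bp()

    def test_variant_everywhere_every_window_hits(self, toy_reference):
        variant_map = {}
        for contig, segs in toy_reference.contigs.items():
            for seg in segs:
                for off, base in enumerate(seg.seq):
                    col = np.full(4, 0.1 / 3)
                    col["ACGT".index(base)] = 0.9
                    variant_map[(contig, seg.start + off)] = col
        from probgenome import ProbabilisticGenome
        pg = ProbabilisticGenome(toy_reference, variant_map,
                                 provenance="population_vcf")
        stats = dataset_statistics(pg, window_length=8, n_windows=40, seed=3)
        assert stats.windows_with_snv_fraction == 1.0

    def test_planted_density_recovered(self, sim_bundle):
        pg = sim_bundle["genome"]
        stats = dataset_statistics(pg, window_length=100, n_windows=200,
                                   seed=5)
        planted = len(sim_bundle["truth"].loci)
        assert stats.num_snv_loci == planted
        assert stats.snv_fraction == pytest.approx(
            planted / pg.reference.total_bp())
        # density 0.002 within binomial slack
        assert 0.001 < stats.snv_fraction < 0.004

    def test_seeded_reproducibility(self, sim_bundle):
        pg = sim_bundle["genome"]
        a = dataset_statistics(pg, 100, 100, seed=9)
        b = dataset_statistics(pg, 100, 100, seed=9)
        assert a == b

    def test_window_longer_than_genome_errors(self, toy_reference):
        pg = reference_only_genome(toy_reference)
        with pytest.raises(ValueError):
            dataset_statistics(pg, window_length=10_000, n_windows=10,
                               seed=0)
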