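"""Synthetic genome generator: statistical structure and round-trip fidelity."""

import numpy as np
import pytest

from amicoding.profiles import ami_profile, estimate_marginal
from amicoding.sequence_io import build_parent_sequences, reverse_complement
from amicoding.synthetic import (
    CodonUsageTable,
    GENETIC_CODE,
    NoncodingModel,
    SENSE_CODONS,
    STOP_CODONS,
    SyntheticGenomeSpec,
    SyntheticError,
    generate_annotated_genome,
    generate_coding_parent,
    generate_noncoding_parent,
    gtf_lines,
)


class TestCodonTable:
    def test_sense_codons(self):
        assert len(SENSE_CODONS) == 61
        assert not set(STOP_CODONS) & set(SENSE_CODONS)
        assert set(GENETIC_CODE) == set(SENSE_CODONS)

    def test_weights_normalized(self):
        for table in (CodonUsageTable.uniform(), CodonUsageTable.biased()):
            assert table.weights.sum() == pytest.approx(1.0)
            assert (table.weights >= 0).all()

    def test_biased_table_prefers_gc_ending(self):
        table = CodonUsageTable.biased(8.0)
        w = dict(zip(SENSE_CODONS, table.weights))
        assert w["GCC"] / w["GCA"] == pytest.approx(8.0)  # Ala: GCC pref, GCA not
        assert w["AAG"] / w["AAA"] == pytest.approx(8.0)  # Lys: G/C-ending pref

    def test_degenerate_table(self):
        w = np.zeros(61)
        w[SENSE_CODONS.index("ATG")] = 1.0
        table = CodonUsageTable(w)
        assert generate_coding_parent(table, 12, seed=0) == "ATGATGATGATG"

    def test_base_composition_matches_implied_frequencies(self):
        table = CodonUsageTable.uniform()
        seq = generate_coding_parent(table, 99_999, seed=1)
        expected = table.base_frequencies()
        observed = estimate_marginal(seq).probs
        n = len(seq)
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(observed - expected) < 3 * sigma + 1e-9).all()


class TestCodingParent:
    def test_determinism_and_truncation(self):
        table = CodonUsageTable.biased()
        a = generate_coding_parent(table, 1000, seed=5)
        b = generate_coding_parent(table, 1000, seed=5)
        assert a == b and len(a) == 1000

    def test_period_three_ami_structure(self):
        seq = generate_coding_parent(CodonUsageTable.biased(), 120_000, seed=6)
        prof = ami_profile(seq, 9).values
        assert prof[2] > prof[1] and prof[2] > prof[3]  # AMI_3 > AMI_2, AMI_4


class TestNoncodingParent:
    def test_determinism_and_length(self):
        model = NoncodingModel.at_rich()
        a = generate_noncoding_parent(model, 5000, seed=7)
        assert a == generate_noncoding_parent(model, 5000, seed=7)
        assert len(a) == 5000

    def test_stationary_composition(self):
        model = NoncodingModel.at_rich(polyt_rate=0.0)
        seq = generate_noncoding_parent(model, 100_000, seed=8)
        observed = estimate_marginal(seq).probs
        np.testing.assert_allclose(observed, model.initial, atol=0.01)

    def test_plugin_mi_bias_on_iid_null(self):
        # for an i.i.d. uniform sequence the plug-in AMI estimate has a known
        # positive bias of about 9 / (2 N ln 2) bits at N pairs
        model = NoncodingModel.uniform()
        seq = generate_noncoding_parent(model, 100_001, seed=9)
        ami_1 = ami_profile(seq, 1).values[0]
        expected_bias = 9 / (2 * 100_000 * np.log(2))
        assert ami_1 < 3 * expected_bias
        assert ami_1 > expected_bias / 3

    def test_polyt_runs_inserted(self):
        model = NoncodingModel.at_rich(polyt_rate=0.01, polyt_mean_run=10)
        seq = generate_noncoding_parent(model, 50_000, seed=10)
        base = generate_noncoding_parent(
            NoncodingModel.at_rich(polyt_rate=0.0), 50_000, seed=10
        )
        def longest_t_run(s):
            best = cur = 0
            for c in s:
                cur = cur + 1 if c == "T" else 0
                best = max(best, cur)
            return best

        assert longest_t_run(seq) > longest_t_run(base)
        assert seq.count("T") > base.count("T")

    def test_validation(self):
        with pytest.raises(SyntheticError):
            NoncodingModel(np.full((4, 4), 0.3), np.full(4, 0.25))
        with pytest.raises(SyntheticError):
            generate_noncoding_parent(NoncodingModel.uniform(), 0, seed=0)


class TestAnnotatedGenome:
    def test_minimal_genome(self):
        spec = SyntheticGenomeSpec(
            species_id="mini", n_genes=1, gene_length_range=(30, 30),
            intergenic_length_range=(20, 20), seed=1,
        )
        genome = generate_annotated_genome(spec)
        assert len(genome.cds_features) == 1
        contig = genome.contigs["contig1"]
        assert len(contig) == 30 + 2 * 20  # conservation of length
        parents = build_parent_sequences(genome.contigs, genome.cds_features, "mini")
        assert parents.coding == genome.parents.coding
        assert parents.noncoding == genome.parents.noncoding

    def test_minus_strand_gene_recovered(self):
        # find a seed placing the single gene on the minus strand
        for seed in range(20):
            spec = SyntheticGenomeSpec(
                species_id="m", n_genes=1, gene_length_range=(60, 60),
                intergenic_length_range=(25, 25), seed=seed,
            )
            genome = generate_annotated_genome(spec)
            if genome.cds_features[0].interval.strand == "-":
                break
        else:
            pytest.fail("no minus-strand gene in 20 seeds")
        iv = genome.cds_features[0].interval
        embedded = genome.contigs[iv.seqid][iv.start - 1 : iv.end]
        assert reverse_complement(embedded) == genome.parents.coding
        parents = build_parent_sequences(genome.contigs, genome.cds_features, "m")
        assert parents.coding == genome.parents.coding

    def test_round_trip_both_strand_genome(self, toy_genome):
        spec, genome = toy_genome
        strands = {f.interval.strand for f in genome.cds_features}
        assert strands == {"+", "-"}  # both strands exercised
        parents = build_parent_sequences(genome.contigs, genome.cds_features,
                                         spec.species_id)
        assert parents.coding == genome.parents.coding
        assert parents.noncoding == genome.parents.noncoding

    def test_multi_contig_and_determinism(self):
        spec = SyntheticGenomeSpec(species_id="mc", n_genes=7, n_contigs=3, seed=9)
        g1 = generate_annotated_genome(spec)
        g2 = generate_annotated_genome(spec)
        assert list(g1.contigs) == ["contig1", "contig2", "contig3"]
        assert g1.contigs == g2.contigs
        assert sum(1 for _ in g1.cds_features) == 7
        rows = gtf_lines(g1)
        assert all(r.split("\t")[2] == "CDS" for r in rows)
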