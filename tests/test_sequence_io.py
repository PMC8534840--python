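"""FASTA/GTF reading and parent-sequence construction."""

import numpy as np
import pytest

from amicoding.sequence_io import (
    AnnotationError,
    CdsFeature,
    GenomicInterval,
    build_parent_sequences,
    complement_intervals,
    merge_intervals,
    read_cds_features,
    read_fasta,
    read_parents_fasta,
    reverse_complement,
    write_fasta,
    write_parents_fasta,
)

GTF_TOY = """\
chr1\tsrc\tgene\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\tCDS\t4\t9\t.\t+\t0\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t4\t9\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
"""


class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">chr1\nACGT\n")
        assert read_fasta(p) == {"chr1": "ACGT"}

    def test_wrapped_and_lowercase(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">chr1\nacg\ntAC\n>chr2 description text\nGGgg\n")
        assert read_fasta(p) == {"chr1": "ACGTAC", "chr2": "GGGG"}

    def test_malformed(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("ACGT\n")
        with pytest.raises(AnnotationError, match="line 1"):
            read_fasta(p)
        p.write_text("")
        with pytest.raises(AnnotationError, match="empty"):
            read_fasta(p)

    def test_write_read_round_trip(self, tmp_path):
        recs = {"c1": "ACGT" * 40, "c2": "TTTTT"}
        write_fasta(tmp_path / "w.fasta", recs)
        assert read_fasta(tmp_path / "w.fasta") == recs


class TestGtf:
    def test_cds_filter(self, tmp_path):
        p = tmp_path / "toy.gtf"
        p.write_text(GTF_TOY)
        feats = read_cds_features(p)
        assert len(feats) == 1
        assert feats[0].transcript_id == "t1"
        assert feats[0].interval == GenomicInterval("chr1", 4, 9, "+")

    def test_negative_strand_and_shared_exon(self, tmp_path):
        rows = [
            'chr1\ts\tCDS\t10\t30\t.\t-\t0\tgene_id "g1"; transcript_id "t1";',
            'chr1\ts\tCDS\t10\t30\t.\t-\t0\tgene_id "g1"; transcript_id "t2";',
        ]
        p = tmp_path / "neg.gtf"
        p.write_text("\n".join(rows) + "\n")
        feats = read_cds_features(p)
        assert [f.transcript_id for f in feats] == ["t1", "t2"]
        assert all(f.interval.strand == "-" for f in feats)
        assert feats[0].interval == feats[1].interval

    def test_missing_transcript_id_falls_back(self, tmp_path, caplog):
        p = tmp_path / "no_tid.gtf"
        p.write_text('chr1\ts\tCDS\t1\t6\t.\t+\t0\tgene_id "g1";\n')
        with caplog.at_level("WARNING"):
            feats = read_cds_features(p)
        assert feats[0].transcript_id == "row1"
        assert "transcript_id" in caplog.text

    def test_malformed_column_count(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text("chr1\tCDS\t1\t6\n")
        with pytest.raises(AnnotationError, match="line 1"):
            read_cds_features(p)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected", [("CCCAGG", "CCTGGG"), ("AAAA", "TTTT"), ("ACGTN", "NACGT")]
    )
    def test_hand_cases(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_involution(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGTN"), size=200))
        assert reverse_complement(reverse_complement(seq)) == seq


class TestIntervals:
    def test_merge_and_complement(self):
        merged = merge_intervals([(10, 20), (15, 25), (40, 50), (26, 30)])
        assert merged == [(10, 30), (40, 50)]
        comp = complement_intervals(merged, 60)
        assert comp == [(1, 9), (31, 39), (51, 60)]
        # partition property
        total = sum(e - s + 1 for s, e in merged) + sum(e - s + 1 for s, e in comp)
        assert total == 60


class TestParents:
    def _chr(self):
        return {"chr1": "AAACCCAGGTTT"}

    def test_plus_strand_cds(self):
        feats = [CdsFeature("t1", GenomicInterval("chr1", 4, 9, "+"))]
        p = build_parent_sequences(self._chr(), feats, "sp")
        assert p.coding == "CCCAGG"
        # noncoding: 1-3 fwd + rc, then 10-12 fwd + rc, coordinate order
        assert p.noncoding == "AAA" + "TTT" + "TTT" + "AAA"

    def test_minus_strand_cds(self):
        feats = [CdsFeature("t1", GenomicInterval("chr1", 4, 9, "-"))]
        p = build_parent_sequences(self._chr(), feats, "sp")
        assert p.coding == "CCTGGG"

    def test_duplicate_transcripts_deduplicated(self):
        feats = [
            CdsFeature("t1", GenomicInterval("chr1", 4, 9, "+")),
            CdsFeature("t2", GenomicInterval("chr1", 4, 9, "+")),
        ]
        p = build_parent_sequences(self._chr(), feats, "sp")
        assert p.coding == "CCCAGG"
        p = build_parent_sequences(self._chr(), feats, "sp", dedupe=False)
        assert p.coding == "CCCAGGCCCAGG"

    def test_multi_exon_minus_strand_transcript(self):
        # genome 5'->3' on minus strand reads revcomp from the right
        assembly = {"chr1": "TTGGCCAATTGGCCAA"}
        feats = [
            CdsFeature("t1", GenomicInterval("chr1", 3, 6, "-")),
            CdsFeature("t1", GenomicInterval("chr1", 11, 14, "-")),
        ]
        p = build_parent_sequences(assembly, feats, "sp")
        assert p.coding == reverse_complement("GGCC" + "GGCC")

    def test_max_seqs_restriction(self):
        assembly = {"chr1": "AAACCCAGGTTT", "chr2": "GGGGGG"}
        feats = [
            CdsFeature("t1", GenomicInterval("chr1", 4, 9, "+")),
            CdsFeature("t2", GenomicInterval("chr2", 1, 6, "+")),
        ]
        p = build_parent_sequences(assembly, feats, "sp", max_seqs=1)
        assert p.coding == "CCCAGG"
        assert "G" * 6 not in p.coding

    def test_out_of_bounds_feature(self):
        feats = [CdsFeature("t1", GenomicInterval("chr1", 4, 99, "+"))]
        with pytest.raises(AnnotationError, match="t1"):
            build_parent_sequences(self._chr(), feats, "sp")

    def test_empty_parents_error(self):
        with pytest.raises(AnnotationError, match="coding"):
            build_parent_sequences(self._chr(), [], "sp")
        feats = [CdsFeature("t1", GenomicInterval("chr1", 1, 12, "+"))]
        with pytest.raises(AnnotationError, match="noncoding"):
            build_parent_sequences(self._chr(), feats, "sp")

    def test_partition_property_on_synthetic_genome(self, toy_genome):
        _, genome = toy_genome
        for sid, contig in genome.contigs.items():
            covered = merge_intervals(
                (f.interval.start, f.interval.end)
                for f in genome.cds_features
                if f.interval.seqid == sid
            )
            comp = complement_intervals(covered, len(contig))
            total = sum(e - s + 1 for s, e in covered) + sum(
                e - s + 1 for s, e in comp
            )
            assert total == len(contig)


def test_parents_fasta_round_trip(tmp_path):
    from amicoding.sequence_io import ParentSequences

    parents = ParentSequences("sp", "ACGT" * 30, "TTTT" * 30)
    write_parents_fasta(tmp_path / "p.fasta", parents)
    back = read_parents_fasta(tmp_path / "p.fasta", "sp")
    assert back == parents
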