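"""GFF3 hierarchy parsing, intron inference and representative selection."""

import pytest

from genestats.annotation_io import (infer_introns, parse_gff3,
                                     select_representative)
from genestats.errors import ConsistencyError, GffParseError, HierarchyError
from genestats.models import GeneModel, GenomicInterval, TranscriptModel

MINIMAL = """\
##gff-version 3
s1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1
s1\tsrc\tmRNA\t100\t200\t.\t+\t.\tID=t1;Parent=g1
s1\tsrc\texon\t100\t200\t.\t+\t.\tParent=t1
"""


def write(tmp_path, text, name="test.gff3"):
    path = tmp_path / name
    path.write_text(text)
    return str(path)


class TestParseGff3:
    def test_minimal_hierarchy(self, tmp_path):
        parsed = parse_gff3(write(tmp_path, MINIMAL))
        assert len(parsed.genes) == 1
        (gene,) = parsed.genes
        (tx,) = gene.transcripts
        assert len(tx.exons) == 1 and len(tx.introns) == 0
        assert parsed.skipped_count == 0

    def test_gene_without_mrna_skipped_and_counted(self, tmp_path):
        text = MINIMAL + "s1\tsrc\tgene\t300\t400\t.\t+\t.\tID=g2\n"
        parsed = parse_gff3(write(tmp_path, text))
        assert len(parsed.genes) == 1
        assert parsed.skipped_no_mrna == ["g2"]

    def test_fixture_totals_match_generator_truth(self, small_fixture,
                                                  small_analysis):
        truth = small_fixture.truth
        parsed = small_analysis.annotation
        assert len(parsed.genes) == truth.overview["gene_count"]
        reps = truth.representative_by_mode["longest"]
        for gene in parsed.genes:
            assert gene.representative.id == reps[gene.id]
            # per-transcript structure equals recorded truth
            detail = truth.per_transcript[gene.representative.id]
            assert [e.length() for e in gene.representative.exons] == \
                detail["exon_lengths"]
            assert [i.length() for i in gene.representative.introns] == \
                detail["intron_lengths"]

    def test_malformed_column_count_names_line(self, tmp_path):
        text = MINIMAL + "s1\tsrc\tgene\t300\n"
        with pytest.raises(GffParseError, match="line 5"):
            parse_gff3(write(tmp_path, text))

    def test_orphan_mrna_rejected(self, tmp_path):
        text = MINIMAL + "s1\tsrc\tmRNA\t300\t400\t.\t+\t.\tID=t9;Parent=gX\n"
        with pytest.raises(HierarchyError, match="t9"):
            parse_gff3(write(tmp_path, text))

    def test_duplicate_gene_id_rejected(self, tmp_path):
        text = MINIMAL + "s2\tsrc\tgene\t10\t20\t.\t+\t.\tID=g1\n"
        with pytest.raises(HierarchyError, match="duplicate"):
            parse_gff3(write(tmp_path, text))

    def test_exon_on_other_seqid_rejected(self, tmp_path):
        text = (
            "s1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1\n"
            "s1\tsrc\tmRNA\t100\t200\t.\t+\t.\tID=t1;Parent=g1\n"
            "s2\tsrc\texon\t100\t200\t.\t+\t.\tParent=t1\n"
        )
        with pytest.raises(ConsistencyError):
            parse_gff3(write(tmp_path, text))

    def test_reparsing_yields_identical_models(self, small_fixture):
        first = parse_gff3(str(small_fixture.gff3_path))
        second = parse_gff3(str(small_fixture.gff3_path))
        assert first.genes == second.genes


def _tx(exon_coords, strand="+"):
    return TranscriptModel(
        id="t1", gene_id="g1",
        exons=[GenomicInterval("s1", a, b, strand) for a, b in exon_coords],
    )


class TestInferIntrons:
    def test_single_gap_yields_one_intron(self):
        tx = infer_introns(_tx([(1, 10), (21, 30)]))
        assert [(i.start, i.end) for i in tx.introns] == [(11, 20)]
        assert tx.introns[0].length() == 10

    def test_single_exon_has_no_introns(self):
        assert infer_introns(_tx([(1, 10)])).introns == []

    def test_zero_gap_emits_no_intron(self, caplog):
        tx = infer_introns(_tx([(1, 10), (11, 20)]))
        assert tx.introns == []

    def test_overlapping_exons_rejected_naming_transcript(self):
        with pytest.raises(ConsistencyError, match="t1"):
            infer_introns(_tx([(1, 10), (5, 20)]))

    def test_span_conservation(self, small_analysis):
        """genomic span == sum(exons) + sum(introns) for every analyzed
        transcript (requires no zero-gap exon pairs, which the generator
        never emits)."""
        for gene in small_analysis.annotation.genes:
            for tx in gene.transcripts:
                assert tx.genomic_length == tx.spliced_length + tx.intron_length


def _gene(lengths_ids):
    transcripts = [
        TranscriptModel(id=tid, gene_id="g",
                        exons=[GenomicInterval("s1", 1, length, "+")])
        for length, tid in lengths_ids
    ]
    return GeneModel(id="g", transcripts=transcripts, seqid="s1", strand="+")


class TestSelectRepresentative:
    def test_longest_of_two(self):
        gene = _gene([(300, "a"), (500, "b")])
        assert select_representative(gene, "longest").id == "b"
        assert gene.representative.id == "b"

    def test_shortest_of_two(self):
        assert select_representative(_gene([(300, "a"), (500, "b")]),
                                     "shortest").id == "a"

    def test_median_takes_lower_middle_for_even_counts(self):
        gene = _gene([(100, "a"), (200, "b"), (300, "c"), (400, "d")])
        assert select_representative(gene, "median").id == "b"

    def test_tie_break_by_lexicographically_smallest_id(self):
        gene = _gene([(250, "mRNA-b"), (250, "mRNA-a")])
        assert select_representative(gene, "longest").id == "mRNA-a"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            select_representative(_gene([(10, "a")]), "widest")

    def test_one_representative_per_gene(self, small_analysis):
        genes = small_analysis.annotation.genes
        assert len(small_analysis.transcript_rows) == len(genes)
        for gene in genes:
            assert gene.representative in gene.transcripts
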