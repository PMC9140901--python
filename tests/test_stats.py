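"""GC content and annotation summary statistics."""

import logging

import pytest
from scipy import stats as sps

import mitoforms as mf
from mitoforms.stats import AnnotationRecord, parse_genbank, parse_gff3, summarize_annotation

from conftest import random_dna


class TestGC:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 100.0), ("ATGC", 50.0), ("AATT", 0.0)])
    def test_simple_compositions(self, seq, expected):
        assert mf.gc_content(seq) == expected

    def test_ambiguous_bases_excluded_from_denominator(self):
        assert mf.gc_content("GGNNCC") == 100.0

    def test_all_n_is_undefined(self):
        assert mf.gc_content("NNNN") is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mf.gc_content("")

    def test_synthetic_genome_matches_spec_within_binomial_bounds(self, rng):
        n, gc = 50_000, 0.4554
        seq = random_dna(rng, n, gc=gc)
        lo, hi = sps.binom.ppf([0.005, 0.995], n, gc)
        observed = mf.gc_content(seq) / 100 * n
        assert lo <= observed <= hi


GENOME = "".join("ACGT"[i % 4] for i in range(3000))


def _records():
    return [
        AnnotationRecord("nad1", "CDS", "+", ((100, 400), (600, 900), (1100, 1300))),
        AnnotationRecord("cox1", "CDS", "-", ((1500, 2100),)),
        AnnotationRecord("trnM-CAU", "tRNA", "+", ((2200, 2272),)),
        AnnotationRecord("rrn18", "rRNA", "+", ((2300, 2800),)),
    ]


class TestSummarize:
    def test_hand_computed_totals(self):
        genome = mf.CircularSequence("g", GENOME)
        st, table = summarize_annotation(_records(), genome)
        assert st.n_protein_coding == 2 and st.n_trna == 1 and st.n_rrna == 1
        assert st.coding_bp == 300 + 300 + 200 + 600
        assert st.noncoding_rna_bp == 72 + 500
        assert st.intron_count == 2  # 3 exons -> 2 introns
        assert st.genes_with_introns == ("nad1",)
        assert set(table["functional_class"]) == {
            "Complex I (NADH dehydrogenase)",
            "Complex IV (cytochrome c oxidase)",
            "Transfer RNAs",
            "Ribosomal RNAs",
        }

    def test_overlapping_cds_counted_once(self):
        genome = mf.CircularSequence("g", GENOME)
        recs = [
            AnnotationRecord("atp1", "CDS", "+", ((100, 500),)),
            AnnotationRecord("atp2", "CDS", "-", ((300, 700),)),
        ]
        st, _ = summarize_annotation(recs, genome)
        assert st.coding_bp == 600  # union, not 800

    def test_empty_annotation_yields_zeros(self):
        genome = mf.CircularSequence("g", GENOME)
        st, table = summarize_annotation([], genome)
        assert st.n_protein_coding == 0 and st.coding_bp == 0 and st.intron_count == 0
        assert table.empty

    def test_out_of_genome_record_rejected_and_logged(self, caplog):
        genome = mf.CircularSequence("g", GENOME)
        recs = [AnnotationRecord("nad9", "CDS", "+", ((2900, 3300),))]
        with caplog.at_level(logging.WARNING):
            st, _ = summarize_annotation(recs, genome)
        assert st.n_protein_coding == 0
        assert "nad9" in caplog.text

    def test_three_exon_gene_contributes_two_introns(self):
        genome = mf.CircularSequence("g", GENOME)
        recs = [AnnotationRecord("nad7", "CDS", "+", ((0, 100), (200, 300), (400, 500)))]
        st, _ = summarize_annotation(recs, genome)
        assert st.intron_count == 2

    def test_overlapping_exons_within_gene_rejected(self):
        with pytest.raises(ValueError):
            AnnotationRecord("bad", "CDS", "+", ((0, 100), (50, 150)))


GFF3 = """##gff-version 3
chr1\ttest\tgene\t101\t1300\t.\t+\t.\tID=gene_nad1
chr1\ttest\tCDS\t101\t400\t.\t+\t0\tID=cds_nad1_1;Parent=gene_nad1;gene=nad1
chr1\ttest\tCDS\t601\t900\t.\t+\t0\tID=cds_nad1_2;Parent=gene_nad1;gene=nad1
chr1\ttest\tCDS\t1101\t1300\t.\t+\t0\tID=cds_nad1_3;Parent=gene_nad1;gene=nad1
chr1\ttest\tCDS\t1501\t2100\t.\t-\t0\tID=cds_cox1;gene=cox1
chr1\ttest\ttRNA\t2201\t2272\t.\t+\t.\tID=trn1;gene=trnM-CAU
chr1\ttest\trRNA\t2301\t2800\t.\t+\t.\tID=rrn1;gene=rrn18
"""

GENBANK_FEATURES = """LOCUS       chr1                    3000 bp    DNA     circular PLN 01-JAN-2024
DEFINITION  synthetic test molecule.
ACCESSION   chr1
FEATURES             Location/Qualifiers
     source          1..3000
     CDS             join(101..400,601..900,1101..1300)
                     /gene="nad1"
     CDS             complement(1501..2100)
                     /gene="cox1"
     tRNA            2201..2272
                     /gene="trnM-CAU"
     rRNA            2301..2800
                     /gene="rrn18"
ORIGIN
{origin}
//
"""


def _genbank_text():
    lines = []
    for i in range(0, 3000, 60):
        chunk = GENOME[i : i + 60]
        parts = " ".join(chunk[j : j + 10].lower() for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {parts}")
    return GENBANK_FEATURES.format(origin="\n".join(lines))


class TestParsers:
    def test_gff3_and_genbank_yield_identical_stats(self, tmp_path):
        gff = tmp_path / "ann.gff3"
        gff.write_text(GFF3)
        gbk = tmp_path / "ann.gbk"
        gbk.write_text(_genbank_text())
        genome = mf.CircularSequence("chr1", GENOME)
        st_gff, _ = summarize_annotation(parse_gff3(gff), genome)
        st_gbk, _ = summarize_annotation(parse_genbank(gbk), genome)
        assert st_gff == st_gbk
        assert st_gff == summarize_annotation(_records(), genome)[0]

    def test_read_annotation_dispatches_on_format(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(GFF3)
        gbk = tmp_path / "a.gbk"
        gbk.write_text(_genbank_text())
        assert len(mf.read_annotation(gff)) == len(mf.read_annotation(gbk)) == 4
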