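"""Gene/transcript model, annotation I/O and family-filter tests."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeosplice.models import (
    AnnotationFormatError,
    DomainHit,
    GeneModel,
    JunctionChain,
    TranscriptModel,
    ValidationError,
    annotation_report,
    family_filter,
    introns_of,
    read_annotation,
    spliced_sequence,
    write_annotation,
)

GTF_ONE_GENE = """\
chr1\tsrc\tgene\t101\t400\t.\t+\t.\tgene_id "g1";
chr1\tsrc\ttranscript\t101\t400\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";
chr1\tsrc\ttranscript\t101\t400\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t2";
chr1\tsrc\texon\t101\t150\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t2";
chr1\tsrc\texon\t201\t250\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t2";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t2";
"""

GFF3_ONE_GENE = """\
chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=g1.t1
chr1\tsrc\texon\t301\t400\t.\t+\t.\tParent=g1.t1
"""


class TestReadAnnotation:
    def test_gtf_groups_transcripts_under_gene(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_ONE_GENE)
        genes = read_annotation(p)
        assert len(genes) == 1
        assert [t.transcript_id for t in genes[0].transcripts] == ["g1.t1", "g1.t2"]
        assert sum(t.n_exons for t in genes[0].transcripts) == 5

    def test_coordinate_conversion_is_half_open(self, tmp_path):
        """1-based inclusive 101-200 and 301-400 become [100,200), [300,400)
        with intron chain [[200,300)]."""
        p = tmp_path / "a.gtf"
        p.write_text(GTF_ONE_GENE)
        t1 = read_annotation(p)[0].transcript("g1.t1")
        assert t1.exons == ((100, 200), (300, 400))
        assert tuple(t1.introns()) == ((200, 300),)

    def test_gff3_dialect(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF3_ONE_GENE)
        genes = read_annotation(p)
        assert genes[0].gene_id == "g1"
        assert genes[0].transcripts[0].exons == ((100, 200), (300, 400))

    def test_transcript_under_two_genes_rejected(self, tmp_path):
        bad = GTF_ONE_GENE + (
            'chr1\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "g2"; transcript_id "g1.t1";\n'
        )
        p = tmp_path / "bad.gtf"
        p.write_text(bad)
        with pytest.raises(ValidationError, match="g1.t1"):
            read_annotation(p)

    def test_exon_outside_gene_span_rejected(self, tmp_path):
        bad = GTF_ONE_GENE.replace(
            'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";',
            'chr1\tsrc\texon\t301\t450\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";',
            1,
        )
        p = tmp_path / "bad.gtf"
        p.write_text(bad)
        with pytest.raises(ValidationError, match="g1.t1"):
            read_annotation(p)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(GTF_ONE_GENE + "chr1\tnot-enough-columns\n")
        with pytest.raises(AnnotationFormatError, match=":9"):
            read_annotation(p)

    def test_round_trip_preserves_exons(self, tmp_path, small_sim):
        sim = small_sim[0]
        p = tmp_path / "rt.gtf"
        write_annotation(sim.isoform_annotation, p)
        back = read_annotation(p)
        orig = {
            t.transcript_id: t.exons
            for g in sim.isoform_annotation
            for t in g.transcripts
        }
        got = {t.transcript_id: t.exons for g in back for t in g.transcripts}
        assert got == orig
        # gene metadata survives too
        assert {g.gene_id: (g.subgenome, g.triad_id) for g in back} == {
            g.gene_id: (g.subgenome, g.triad_id) for g in sim.isoform_annotation
        }


class TestTranscriptModel:
    @pytest.mark.parametrize(
        "exons,expected",
        [
            (((100, 200), (300, 400), (500, 600)), ((200, 300), (400, 500))),
            (((100, 600),), ()),
        ],
    )
    def test_introns_of(self, exons, expected):
        t = TranscriptModel("t", "c", "+", exons)
        assert tuple(introns_of(t)) == expected

    def test_touching_exons_rejected(self):
        with pytest.raises(ValidationError, match="touch"):
            TranscriptModel("t", "c", "+", ((0, 50), (50, 100)))

    @given(
        st.lists(st.integers(0, 500), min_size=2, max_size=12, unique=True)
    )
    @settings(max_examples=100, deadline=None)
    def test_span_plus_introns_reconstructs_exons(self, cuts):
        # any strictly increasing even-length boundary list defines exons
        cuts = sorted(cuts)
        if len(cuts) % 2:
            cuts = cuts[:-1]
        exons = tuple((cuts[i], cuts[i + 1]) for i in range(0, len(cuts), 2))
        try:
            t = TranscriptModel("t", "c", "+", exons)
        except ValidationError:
            return  # touching/zero-length intervals are invalid inputs
        rebuilt = TranscriptModel.from_span_and_introns(
            "t", "c", "+", t.span, t.introns()
        )
        assert rebuilt.exons == t.exons


class TestSplicedSequence:
    GENOME = {"c": "AAACCCGGG"}

    def test_plus_strand_concatenates(self):
        t = TranscriptModel("t", "c", "+", ((0, 3), (6, 9)))
        assert spliced_sequence(t, self.GENOME) == "AAAGGG"

    def test_minus_strand_reverse_complements(self):
        t = TranscriptModel("t", "c", "-", ((0, 3), (6, 9)))
        assert spliced_sequence(t, self.GENOME) == "CCCTTT"

    def test_out_of_bounds_rejected(self):
        t = TranscriptModel("t", "c", "+", ((0, 20),))
        with pytest.raises(ValidationError):
            spliced_sequence(t, self.GENOME)

    def test_missing_chromosome(self):
        t = TranscriptModel("t", "nope", "+", ((0, 3),))
        with pytest.raises(KeyError):
            spliced_sequence(t, self.GENOME)


class TestFamilyFilter:
    REQUIRED = {"HATPase_c", "HSP90"}

    def test_both_domains_from_mixed_sources_retained(self):
        hits = [
            DomainHit("p1", "HATPase_c", "hmmer", 1e-10),
            DomainHit("p1", "HSP90", "blast", 1e-20, 80.0),
        ]
        assert family_filter(hits, self.REQUIRED) == {"p1"}

    def test_single_domain_excluded(self):
        hits = [DomainHit("p2", "HSP90", "blast", 1e-20, 80.0)]
        assert family_filter(hits, self.REQUIRED) == set()

    def test_duplicate_evidence_deduplicated(self):
        hits = [
            DomainHit("p1", "HSP90", "blast", 1e-20, 80.0),
            DomainHit("p1", "HSP90", "hmmer", 1e-12),
            DomainHit("p1", "HATPase_c", "hmmer", 1e-9),
        ]
        out = family_filter(hits, self.REQUIRED)
        assert sorted(out) == ["p1"]

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["p1", "p2", "p3"]),
                st.sampled_from(["HATPase_c", "HSP90", "Other"]),
            ),
            max_size=12,
        ),
        st.tuples(
            st.sampled_from(["p1", "p2", "p3"]),
            st.sampled_from(["HATPase_c", "HSP90"]),
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_evidence(self, pairs, extra):
        """Adding a hit never removes a protein from the result."""
        mk = lambda ps: [DomainHit(p, d, "hmmer", 1e-9) for p, d in ps]
        before = family_filter(mk(pairs), self.REQUIRED)
        after = family_filter(mk(pairs + [extra]), self.REQUIRED)
        assert before <= after


def test_annotation_report_counts(small_sim):
    sim = small_sim[0]
    rep = annotation_report(sim.annotation)
    assert rep["n_genes"] == 6
    assert rep["n_transcripts"] == 6
    assert set(rep["chromosomes"]) == {"chrA", "chrB", "chrD"}
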