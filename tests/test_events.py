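"""AS-event classification, ORF finding and domain-retention tests."""
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeosplice.events import (
    ComparisonError,
    DomainSpan,
    canonical_isoform,
    classify_events,
    domain_retention,
    longest_orf,
)
from homeosplice.models import TranscriptModel

CANON_EXONS = ((0, 100), (200, 300), (400, 500))


def tx(exons, strand="+", tid="t", chrom="c"):
    return TranscriptModel(tid, chrom, strand, tuple(exons))


class TestClassifyEvents:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_identical_transcripts_give_no_events(self, strand):
        a = tx(CANON_EXONS, strand)
        assert classify_events(a, a) == []

    def test_terminal_extent_differences_ignored(self):
        iso = tx(((50, 100), (200, 300), (400, 450)))
        assert classify_events(iso, tx(CANON_EXONS)) == []

    @pytest.mark.parametrize(
        "strand,intron_tx_index",
        [("+", 1), ("-", 2)],
    )
    def test_intron_retention(self, strand, intron_tx_index):
        """Retaining genomic intron (100,200) is transcription-order
        intron 1 on '+' and intron 2 on '-'."""
        iso = tx(((0, 300), (400, 500)), strand)
        events = classify_events(iso, tx(CANON_EXONS, strand))
        assert [(e.type, e.index, e.delta_bp) for e in events] == [
            ("IR", intron_tx_index, 100)
        ]

    @pytest.mark.parametrize("strand,exon_tx_index", [("+", 2), ("-", 2)])
    def test_exon_skipping(self, strand, exon_tx_index):
        iso = tx(((0, 100), (400, 500)), strand)
        events = classify_events(iso, tx(CANON_EXONS, strand))
        assert [(e.type, e.index, e.delta_bp) for e in events] == [
            ("ES", exon_tx_index, 100)
        ]

    def test_alt_boundary_oracle_all_strand_shift_combinations(self):
        """Exhaustive check of the donor/acceptor rule: shifting the
        genomic start of an intron is a donor (Alt5) change on '+' and an
        acceptor (Alt3) change on '-', and vice versa for the end."""
        for strand, side, delta in itertools.product(
            "+-", ("start", "end"), (-20, -6, 6, 20)
        ):
            intron = [100, 200]
            if side == "start":
                intron[0] += delta
            else:
                intron[1] += delta
            iso = tx(((0, intron[0]), (intron[1], 300)), strand)
            canonical = tx(((0, 100), (200, 300)), strand)
            events = classify_events(iso, canonical)
            expected_type = {
                ("+", "start"): "Alt5",
                ("+", "end"): "Alt3",
                ("-", "start"): "Alt3",
                ("-", "end"): "Alt5",
            }[(strand, side)]
            assert [(e.type, e.index, e.delta_bp) for e in events] == [
                (expected_type, 1, abs(delta))
            ], (strand, side, delta)

    def test_double_shift_gives_both_alt_events_donor_first(self):
        iso = tx(((0, 94), (206, 300)), "+")
        canonical = tx(((0, 100), (200, 300)), "+")
        events = classify_events(iso, canonical)
        assert [(e.type, e.index, e.delta_bp) for e in events] == [
            ("Alt5", 1, 6),
            ("Alt3", 1, 6),
        ]

    CASES = [
        (((0, 94), (206, 300), (400, 500)), CANON_EXONS),
        (((0, 300), (400, 500)), CANON_EXONS),
        (((0, 100), (400, 500)), CANON_EXONS),
        (((0, 100), (230, 300), (400, 500)), CANON_EXONS),
    ]

    def test_strand_flip_swaps_donor_and_acceptor_labels(self):
        """The same genomic structure read on the opposite strand swaps
        Alt5<->Alt3 (donor and acceptor sides exchange) and preserves
        IR/ES types and deltas."""
        swap = {"Alt5": "Alt3", "Alt3": "Alt5", "IR": "IR", "ES": "ES"}
        for iso_exons, can_exons in self.CASES:
            fwd = classify_events(tx(iso_exons, "+"), tx(can_exons, "+"))
            rev = classify_events(tx(iso_exons, "-"), tx(can_exons, "-"))
            assert sorted((swap[e.type], e.delta_bp) for e in fwd) == sorted(
                (e.type, e.delta_bp) for e in rev
            )

    def test_reflection_with_strand_flip_is_an_identity(self):
        """Mirroring all coordinates and flipping the strand produces a
        biologically identical gene, so the classified events (type,
        transcription-order index and delta) are unchanged."""
        L = 1000
        reflect = lambda exons: tuple(sorted((L - e, L - s) for s, e in exons))
        for iso_exons, can_exons in self.CASES:
            fwd = classify_events(tx(iso_exons, "+"), tx(can_exons, "+"))
            rev = classify_events(
                tx(reflect(iso_exons), "-"), tx(reflect(can_exons), "-")
            )
            assert [(e.type, e.index, e.delta_bp) for e in fwd] == [
                (e.type, e.index, e.delta_bp) for e in rev
            ]

    def test_unmatched_difference_reported_as_complex(self):
        # both boundaries of one intron shifted AND overlapping two introns
        iso = tx(((0, 50), (350, 500)),)
        events = classify_events(iso, tx(CANON_EXONS))
        assert all(e.type == "complex" for e in events)
        assert events  # not silently dropped

    def test_disjoint_spans_rejected(self):
        with pytest.raises(ComparisonError):
            classify_events(tx(((1000, 1100),)), tx(CANON_EXONS))

    def test_planted_events_recovered_with_no_false_positives(self, small_sim):
        sim = small_sim[0]
        for gene in sim.isoform_annotation:
            canonical = gene.transcript(f"{gene.gene_id}.1")
            for t in gene.transcripts:
                got = classify_events(t, canonical)
                planted = sim.truth.events[t.transcript_id]
                assert [(e.type, e.index, e.delta_bp) for e in got] == [
                    (e.type, e.index, e.delta_bp) for e in planted
                ], t.transcript_id


class TestLongestOrf:
    def test_simple_orf(self):
        orf = longest_orf("ATGAAATAA", min_orf_codons=1)
        assert (orf.start, orf.end, orf.peptide) == (0, 9, "MK")

    def test_no_orf(self):
        assert longest_orf("CCCCCC", min_orf_codons=1) is None

    def test_min_length_filter(self):
        assert longest_orf("ATGAAATAA", min_orf_codons=30) is None

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            longest_orf("ATGXXXTAA")

    @staticmethod
    def brute_force(seq, min_codons):
        """Enumerate every (ATG, in-frame stop) pair; longest wins, ties to
        the 5'-most start."""
        stops = {"TAA", "TAG", "TGA"}
        best = None
        for start in range(len(seq) - 2):
            if seq[start : start + 3] != "ATG":
                continue
            for end in range(start + 3, len(seq) - 2, 3):
                if seq[end : end + 3] in stops:
                    length = end + 3 - start
                    if length // 3 - 1 >= min_codons and (
                        best is None
                        or length > best[1] - best[0]
                        or (length == best[1] - best[0] and start < best[0])
                    ):
                        best = (start, end + 3)
                    break
        return best

    @given(st.text(alphabet="ACGT", min_size=10, max_size=90))
    @settings(max_examples=300, deadline=None)
    def test_matches_bruteforce_enumeration(self, seq):
        got = longest_orf(seq, min_orf_codons=2)
        expected = self.brute_force(seq, 2)
        if expected is None:
            assert got is None
        else:
            assert (got.start, got.end) == expected

    def test_tie_broken_toward_five_prime(self):
        # two 3-codon ORFs in different frames; the earlier start wins
        seq = "ATGAAAAAATAAC" + "ATGCCCCCCTAA"
        orf = longest_orf(seq, min_orf_codons=2)
        assert orf.start == 0


class TestDomainRetention:
    def test_canonical_retains_everything(self, aa_triad):
        genes, genome, domains = aa_triad
        for g in genes:
            can = canonical_isoform(g, genome)
            assert domain_retention(can, can, domains[g.gene_id], genome) == {
                "HATPase_c",
                "HSP90",
            }

    def test_novel_isoforms_keep_only_the_3prime_domain(self, aa_triad):
        """Each homeolog's novel major isoform encodes a truncated peptide
        with the client-binding (HSP90) domain but not the ATPase domain."""
        genes, genome, domains = aa_triad
        for g in genes:
            can = canonical_isoform(g, genome)
            nimi = g.transcript(f"{g.gene_id}.nimi")
            assert domain_retention(nimi, can, domains[g.gene_id], genome) == {
                "HSP90"
            }

    def test_frameshifting_retention_upstream_of_domains_loses_both(self):
        """A retained 4-bp intron placing a premature stop upstream of both
        domains leaves no translatable domain (translate-and-inspect)."""
        # exon1: 3 codons; 4-bp intron starting with an in-frame TAA;
        # exon2: 30 codons ending in TAA; both domains inside exon 2
        exon2 = "".join(["GGT"] * 29) + "TAA"
        genome = {"c": "ATGGGTCCT" + "TAAC" + exon2}
        canonical = tx(((0, 9), (13, 103)), tid="can")
        iso = tx(((0, 103),), tid="ir")
        domains = [
            DomainSpan("g", "D5", 5, 10),
            DomainSpan("g", "D3", 15, 25),
        ]
        assert domain_retention(canonical, canonical, domains, genome, 5) == {
            "D5",
            "D3",
        }
        assert domain_retention(iso, canonical, domains, genome, 5) == set()

    def test_retained_domains_subset_of_annotated(self, small_sim):
        sim = small_sim[0]
        for gene in sim.isoform_annotation:
            can = gene.transcript(f"{gene.gene_id}.1")
            names = {d.domain_name for d in sim.domains[gene.gene_id]}
            for t in gene.transcripts:
                got = domain_retention(t, can, sim.domains[gene.gene_id], sim.genome)
                assert got <= names
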