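"""Isoform collapse, filtering and novelty-labelling tests."""
import itertools

import numpy as np
import pytest

from homeosplice.collapse import (
    AlignedRead,
    collapse_flnc,
    filter_catalog,
    label_novelty,
    read_bed12,
    write_bed12,
)
from homeosplice.models import GeneModel, TranscriptModel, ValidationError


def mk_read(rid, blocks, chrom="c", strand="+", identity=1.0):
    return AlignedRead(rid, chrom, strand, tuple(blocks), identity)


class TestCollapse:
    def test_shared_chain_collapses_with_union_extents(self):
        r1 = mk_read("r1", [(100, 200), (300, 400), (500, 620)])
        r2 = mk_read("r2", [(120, 200), (300, 400), (500, 600)])
        out = collapse_flnc([r1, r2])
        assert len(out) == 1
        cand = out[0]
        assert cand.support == 2
        assert cand.transcript.span == (100, 620)
        assert tuple(cand.chain) == ((200, 300), (400, 500))

    def test_different_chains_stay_separate(self):
        r1 = mk_read("r1", [(100, 200), (300, 400)])
        r2 = mk_read("r2", [(100, 210), (300, 400)])
        out = collapse_flnc([r1, r2])
        assert len(out) == 2
        assert all(c.support == 1 for c in out)

    def test_mono_exonic_single_linkage_example(self):
        reads = [
            mk_read("r1", [(0, 900)]),
            mk_read("r2", [(100, 1000)]),
            mk_read("r3", [(2000, 3000)]),
        ]
        out = collapse_flnc(reads, mono_end_tolerance=100)
        supports = sorted(c.support for c in out)
        assert supports == [1, 2]

    def test_same_read_id_on_two_chromosomes_rejected(self):
        r1 = mk_read("r1", [(0, 100)], chrom="c1")
        r2 = mk_read("r1", [(0, 100)], chrom="c2")
        with pytest.raises(ValidationError, match="r1"):
            collapse_flnc([r1, r2])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mono_clustering_matches_bruteforce_oracle(self, seed):
        """Single-linkage clusters equal the connected components of the
        'overlapping and both ends within tolerance' graph."""
        rng = np.random.default_rng(seed)
        tol = 100
        reads = []
        for i in range(25):
            s = int(rng.integers(0, 2000))
            e = s + int(rng.integers(200, 1200))
            reads.append(mk_read(f"r{i}", [(s, e)]))

        def linked(a, b):
            (s1, e1), (s2, e2) = a.span, b.span
            return (
                s1 < e2 and s2 < e1 and abs(s1 - s2) <= tol and abs(e1 - e2) <= tol
            )

        # brute-force connected components
        parent = list(range(len(reads)))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i, j in itertools.combinations(range(len(reads)), 2):
            if linked(reads[i], reads[j]):
                parent[find(i)] = find(j)
        expected = {}
        for i in range(len(reads)):
            expected.setdefault(find(i), set()).add(reads[i].read_id)
        expected_sets = sorted(map(frozenset, expected.values()), key=sorted)

        out = collapse_flnc(reads, mono_end_tolerance=tol)
        got_supports = sorted(c.support for c in out)
        assert got_supports == sorted(len(s) for s in expected_sets)

    def test_collapse_is_idempotent(self, small_sim):
        """Expanding candidates back into one read each and re-collapsing
        yields the same candidate chain set."""
        _, reads, _, _, _ = small_sim
        first = collapse_flnc(reads)
        expanded = [
            mk_read(
                f"x{i}",
                c.transcript.exons,
                chrom=c.transcript.chromosome,
                strand=c.transcript.strand,
                identity=c.mean_identity,
            )
            for i, c in enumerate(first)
        ]
        second = collapse_flnc(expanded)
        key = lambda c: (
            c.transcript.chromosome,
            c.transcript.strand,
            c.transcript.span,
            tuple(c.chain),
        )
        assert sorted(map(key, first)) == sorted(map(key, second))

    def test_support_is_conserved(self, small_sim):
        _, reads, _, _, _ = small_sim
        out = collapse_flnc(reads)
        assert sum(c.support for c in out) == len(reads)


class TestFilter:
    ANNOT = [
        GeneModel(
            "g1",
            "c",
            "+",
            (0, 1000),
            (TranscriptModel("g1.t1", "c", "+", ((0, 200), (400, 1000)), "g1"),),
        )
    ]

    def make_candidates(self, reads):
        return collapse_flnc(reads)

    def test_low_support_removed(self):
        cands = self.make_candidates([mk_read("r1", [(0, 200), (400, 900)])])
        assert filter_catalog(cands, {("c", 200, 400)}, self.ANNOT, min_support=2) == []

    def test_unverified_junction_removed(self):
        reads = [
            mk_read("r1", [(0, 200), (600, 900)]),
            mk_read("r2", [(0, 200), (600, 900)]),
        ]
        cands = self.make_candidates(reads)
        # junction (200,600) neither short-read supported nor annotated
        assert filter_catalog(cands, set(), self.ANNOT) == []

    def test_annotated_junction_passes_without_short_read_support(self):
        reads = [
            mk_read("r1", [(0, 200), (400, 900)], identity=0.99),
            mk_read("r2", [(0, 200), (400, 900)], identity=0.99),
        ]
        cands = self.make_candidates(reads)
        kept = filter_catalog(cands, set(), self.ANNOT)
        assert len(kept) == 1
        assert kept[0].junction_verified == (True,)

    def test_low_identity_removed(self):
        reads = [
            mk_read("r1", [(0, 200), (400, 900)], identity=0.80),
            mk_read("r2", [(0, 200), (400, 900)], identity=0.85),
        ]
        cands = self.make_candidates(reads)
        assert filter_catalog(cands, set(), self.ANNOT, min_identity=0.90) == []

    def test_mono_exonic_needs_no_junction_support(self):
        reads = [mk_read("r1", [(0, 900)]), mk_read("r2", [(10, 890)])]
        cands = self.make_candidates(reads)
        assert len(filter_catalog(cands, set(), self.ANNOT)) == 1


class TestNovelty:
    def test_terminal_extent_differences_do_not_affect_novelty(self):
        """Junction-chain identity alone decides annotated vs novel."""
        annot = TestFilter.ANNOT
        reads = [
            mk_read("r1", [(50, 200), (400, 800)]),
            mk_read("r2", [(50, 200), (400, 800)]),
        ]
        catalog, counts = label_novelty(collapse_flnc(reads), annot)
        assert catalog[0].novelty == "annotated"
        assert counts["g1"] == {"annotated": 1, "novel": 0}

    def test_new_chain_is_novel(self):
        annot = TestFilter.ANNOT
        reads = [mk_read("r1", [(0, 150), (400, 900)])]
        catalog, counts = label_novelty(collapse_flnc(reads), annot)
        assert catalog[0].novelty == "novel"
        assert counts["g1"] == {"annotated": 0, "novel": 1}

    def test_antisense_read_is_unassigned(self):
        annot = TestFilter.ANNOT
        reads = [mk_read("r1", [(0, 200), (400, 900)], strand="-")]
        catalog, counts = label_novelty(collapse_flnc(reads), annot)
        assert catalog[0].gene_id == "unassigned"
        assert "g1" not in counts

    def test_novelty_partitions_catalog(self, small_sim):
        sim, reads, _, _, support = small_sim
        support_set = {
            (r.chrom, int(r.start), int(r.end)) for r in support.itertuples()
        }
        cands = collapse_flnc(reads)
        catalog, counts = label_novelty(
            filter_catalog(cands, support_set, sim.annotation), sim.annotation
        )
        total = sum(v["annotated"] + v["novel"] for v in counts.values())
        assert total == len(catalog)


def test_planted_isoforms_recovered_exactly(small_sim):
    """With perfect identity and depth above the support threshold, the
    filtered catalog's chain set equals the planted set (precision and
    recall both 1)."""
    sim, reads, _, _, support = small_sim
    support_set = {(r.chrom, int(r.start), int(r.end)) for r in support.itertuples()}
    catalog = filter_catalog(collapse_flnc(reads), support_set, sim.annotation)
    got = {
        (c.transcript.chromosome, c.transcript.strand, tuple(c.chain))
        for c in catalog
    }
    planted = {
        (t.chromosome, t.strand, tuple(t.introns()))
        for t in sim.truth.structures.values()
    }
    assert got == planted


def test_bed12_round_trip(tmp_path, small_sim):
    _, reads, _, _, _ = small_sim
    p = tmp_path / "reads.bed"
    write_bed12(reads, p)
    back = read_bed12(p)
    assert [(r.read_id, r.blocks, r.identity) for r in back] == [
        (r.read_id, r.blocks, r.identity) for r in reads
    ]
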