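"""Alternative-splicing event classification and ORF/domain-retention
analysis.

Each catalog isoform is compared against its gene's canonical isoform (the
annotated transcript with the longest complete coding region). Differences
between the two intron chains are classified into the four classical AS
modes — intron retention (IR), exon skipping (ES), and alternative 5'/3'
splice sites (Alt5/Alt3) — with indices reported 1-based in transcription
order. Terminal-exon extent differences are ignored: junction chains alone
define splice-form identity.

A domain annotated on the canonical coding sequence is considered retained
by an isoform when every genomic codon of the domain survives in the
isoform's exons and is translated in the same reading frame by the
isoform's own longest ORF.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .models import (
    AnnotationError,
    GeneModel,
    Interval,
    TranscriptModel,
    spliced_sequence,
)

EVENT_TYPES = ("IR", "ES", "Alt5", "Alt3")


class ComparisonError(ValueError):
    """Transcripts cannot be compared (different genes / disjoint spans)."""


@dataclass(frozen=True, order=True)
class ASEvent:
    """One splicing difference relative to the canonical isoform.

    ``index`` is 1-based in transcription order: for IR/Alt5/Alt3 it is the
    canonical intron index, for ES the canonical exon index. ``delta_bp``
    is the retained-intron length, skipped-exon length, or splice-site
    shift. Differences not matching the four modes are reported with type
    ``complex`` (index -1) and kept out of four-class counts.
    """

    type: str
    index: int
    delta_bp: int

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES + ("complex",):
            raise ValueError(f"unknown event type {self.type!r}")
        if self.delta_bp <= 0:
            raise ValueError("delta_bp must be positive")


def _tx_intron_index(i_genomic: int, n_introns: int, strand: str) -> int:
    """Genomic intron index (0-based) -> transcription-order index (1-based)."""
    return i_genomic + 1 if strand == "+" else n_introns - i_genomic


def _tx_exon_index(i_genomic: int, n_exons: int, strand: str) -> int:
    return i_genomic + 1 if strand == "+" else n_exons - i_genomic


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_events(
    iso: TranscriptModel, canonical: TranscriptModel
) -> list[ASEvent]:
    """Classify the splicing differences of ``iso`` against ``canonical``.

    The two intron chains are compared in genome coordinates:

    * a canonical intron fully covered by an isoform exon -> IR;
    * a canonical internal exon absent from the isoform, with its two
      flanking introns fused into one isoform intron -> ES;
    * an isoform intron overlapping exactly one canonical intron with a
      shifted boundary -> Alt5 when the shifted boundary is the donor side
      in transcription direction, Alt3 when it is the acceptor side (a
      single intron shifted at both ends yields both events).

    Events are returned 5'->3' in transcription order.
    """
    if iso.strand != canonical.strand or iso.chromosome != canonical.chromosome:
        raise ComparisonError("isoform and canonical differ in strand/chromosome")
    if not _overlaps(iso.span, canonical.span):
        raise ComparisonError("isoform and canonical spans do not overlap")
    strand = canonical.strand
    c_int = list(canonical.introns())
    i_int = list(iso.introns())
    n_ci = len(c_int)

    shared = set(c_int) & set(i_int)
    uc = [c for c in c_int if c not in shared]  # unmatched canonical introns
    ui = [i for i in i_int if i not in shared]  # unmatched isoform introns

    events: list[ASEvent] = []

    # intron retention: canonical intron sits wholly inside an isoform exon
    for c in list(uc):
        if any(_overlaps(c, i) for i in ui):
            continue
        if any(es <= c[0] and c[1] <= ee for es, ee in iso.exons):
            events.append(
                ASEvent("IR", _tx_intron_index(c_int.index(c), n_ci, strand), c[1] - c[0])
            )
            uc.remove(c)

    # exon skipping: internal canonical exon with no isoform exon overlap,
    # flanking canonical introns fused into one isoform intron
    for k in range(1, canonical.n_exons - 1):
        ex = canonical.exons[k]
        if any(_overlaps(ex, e) for e in iso.exons):
            continue
        left, right = c_int[k - 1], c_int[k]
        fused = (left[0], right[1])
        if fused in ui and left in uc and right in uc:
            events.append(
                ASEvent(
                    "ES",
                    _tx_exon_index(k, canonical.n_exons, strand),
                    ex[1] - ex[0],
                )
            )
            ui.remove(fused)
            uc.remove(left)
            uc.remove(right)

    # alternative splice sites: 1-to-1 overlapping unmatched intron pairs
    for i in list(ui):
        cands = [c for c in uc if _overlaps(i, c)]
        if len(cands) != 1:
            continue
        c = cands[0]
        if sum(1 for j in ui if _overlaps(c, j)) != 1:
            continue
        idx = _tx_intron_index(c_int.index(c), n_ci, strand)
        d_start = abs(i[0] - c[0])
        d_end = abs(i[1] - c[1])
        if d_start == 0 and d_end == 0:
            continue
        # genomic start boundary is the donor on '+', acceptor on '-'
        if d_start:
            events.append(ASEvent("Alt5" if strand == "+" else "Alt3", idx, d_start))
        if d_end:
            events.append(ASEvent("Alt3" if strand == "+" else "Alt5", idx, d_end))
        ui.remove(i)
        uc.remove(c)

    # anything left is outside the four classical modes
    for leftover in uc + ui:
        events.append(ASEvent("complex", -1, leftover[1] - leftover[0]))

    # 5'->3' transcription order; at one intron the donor-side (Alt5)
    # difference precedes the acceptor-side one
    rank = {"IR": 0, "ES": 0, "Alt5": 0, "Alt3": 1, "complex": 9}
    events.sort(key=lambda e: (e.index if e.index > 0 else 10**9, rank[e.type]))
    return events


# ---------------------------------------------------------------------------
# ORF prediction


@dataclass(frozen=True)
class Orf:
    """An ATG-initiated, stop-terminated open reading frame on a mRNA.

    ``start``/``end`` are 0-based half-open transcript coordinates; ``end``
    includes the stop codon. ``peptide`` excludes the stop.
    """

    start: int
    end: int
    peptide: str

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3


_VALID_MRNA = re.compile(r"^[ACGTN]*$")
_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf(mrna: str, min_orf_codons: int = 30) -> Orf | None:
    """Longest ATG..stop ORF across the three forward frames.

    Ties are broken toward the 5'-most start. Returns None when no ORF of
    at least ``min_orf_codons`` codons (peptide length, excluding the
    stop) exists.
    """
    if not _VALID_MRNA.match(mrna):
        raise ValueError("mRNA must contain only A/C/G/T/N")
    best: tuple[int, int] | None = None  # (-length, start)
    best_coords: tuple[int, int] | None = None
    n = len(mrna)
    for frame in range(3):
        open_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = mrna[pos : pos + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = pos
            elif codon in _STOPS:
                length = pos + 3 - open_start
                key = (-length, open_start)
                if best is None or key < best:
                    best = key
                    best_coords = (open_start, pos + 3)
                open_start = None
    if best_coords is None:
        return None
    start, end = best_coords
    if (end - start) // 3 - 1 < min_orf_codons:
        return None
    peptide = str(Seq(mrna[start : end - 3]).translate())
    return Orf(start, end, peptide)


# ---------------------------------------------------------------------------
# canonical isoform selection


def canonical_isoform(
    gene: GeneModel, genome: Mapping[str, str], min_orf_codons: int = 30
) -> TranscriptModel:
    """The annotated transcript with the longest complete coding region.

    Ties go to the longest spliced transcript, then the smallest id.
    """
    if not gene.transcripts:
        raise ValueError(f"{gene.gene_id}: no transcripts")

    def key(t: TranscriptModel) -> tuple[int, int, str]:
        orf = longest_orf(spliced_sequence(t, genome), min_orf_codons)
        return (-(orf.n_codons if orf else 0), -t.spliced_length, t.transcript_id)

    return min(gene.transcripts, key=key)


# ---------------------------------------------------------------------------
# domain retention


@dataclass(frozen=True)
class DomainSpan:
    """A protein domain as a codon interval on the canonical coding region.

    ``start_codon``/``end_codon`` are 0-based half-open codon indices
    relative to the canonical ORF start.
    """

    gene_id: str
    domain_name: str
    start_codon: int
    end_codon: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_codon < self.end_codon):
            raise ValueError("invalid codon interval")


def read_domain_spans(path: str | Path) -> dict[str, list[DomainSpan]]:
    """Read a ``gene_id domain start_codon end_codon`` TSV."""
    spans: dict[str, list[DomainSpan]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "domain", "start_codon", "end_codon"]:
            raise AnnotationError(f"{path}: unexpected domain-span header {header}")
        for line in fh:
            if not line.strip():
                continue
            gid, dom, s, e = line.rstrip("\n").split("\t")
            spans.setdefault(gid, []).append(DomainSpan(gid, dom, int(s), int(e)))
    return spans


def write_domain_spans(spans: Mapping[str, Sequence[DomainSpan]], path: str | Path) -> None:
    lines = ["gene_id\tdomain\tstart_codon\tend_codon"]
    for gid in sorted(spans):
        for d in spans[gid]:
            lines.append(f"{gid}\t{d.domain_name}\t{d.start_codon}\t{d.end_codon}")
    Path(path).write_text("\n".join(lines) + "\n")


def _tx_to_genome(t: TranscriptModel) -> list[int]:
    """Genomic position of each transcript position, transcription order."""
    positions: list[int] = []
    for s, e in t.exons:
        positions.extend(range(s, e))
    if t.strand == "-":
        positions.reverse()
    return positions


def domain_retention(
    iso: TranscriptModel,
    canonical: TranscriptModel,
    domains: Sequence[DomainSpan],
    genome: Mapping[str, str],
    min_orf_codons: int = 30,
) -> set[str]:
    """Domain names whose every codon survives, in frame, in ``iso``.

    A domain is retained iff each of its genomic codon positions (projected
    through the canonical exon chain) falls inside the isoform's exons and
    is translated at a codon-consistent offset by the isoform's own longest
    ORF. Frameshifting events upstream of a domain therefore abolish it
    unless a downstream start restores the frame.
    """
    can_seq = spliced_sequence(canonical, genome)
    can_orf = longest_orf(can_seq, min_orf_codons)
    if can_orf is None:
        raise AnnotationError(
            f"{canonical.transcript_id}: canonical transcript has no ORF"
        )
    can_map = _tx_to_genome(canonical)
    iso_seq = spliced_sequence(iso, genome)
    iso_orf = longest_orf(iso_seq, min_orf_codons)
    if iso_orf is None:
        return set()
    iso_pos: dict[int, int] = {g: q for q, g in enumerate(_tx_to_genome(iso))}

    retained: set[str] = set()
    for dom in domains:
        tx_start = can_orf.start + 3 * dom.start_codon
        tx_end = can_orf.start + 3 * dom.end_codon
        if tx_end > len(can_map) or tx_end > can_orf.end:
            raise AnnotationError(
                f"domain {dom.domain_name} projects outside the canonical "
                f"ORF of {canonical.transcript_id}"
            )
        ok = True
        for tx in range(tx_start, tx_end, 3):
            g0, g1, g2 = can_map[tx], can_map[tx + 1], can_map[tx + 2]
            try:
                q0, q1, q2 = iso_pos[g0], iso_pos[g1], iso_pos[g2]
            except KeyError:
                ok = False
                break
            if q1 != q0 + 1 or q2 != q0 + 2:
                ok = False
                break
            if q0 < iso_orf.start or q2 >= iso_orf.end - 3:
                ok = False
                break
            if (q0 - iso_orf.start) % 3 != 0:
                ok = False
                break
        if ok:
            retained.add(dom.domain_name)
    return retained
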