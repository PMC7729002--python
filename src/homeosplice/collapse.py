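"""Long-read isoform catalog construction.

Aligned full-length non-chimeric (FLNC) reads that map to the same locus
and share the same splice-junction chain are collapsed into one candidate
isoform. Candidates are then filtered on read support, mean alignment
identity and per-junction verification (short-read support or presence in
the reference annotation), and finally labelled as annotated or novel by
junction-chain identity against the annotated transcripts of the assigned
gene.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .models import (
    GeneModel,
    Interval,
    JunctionChain,
    TranscriptModel,
    ValidationError,
)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AlignedRead:
    """One mapped FLNC read as an exon-block chain with an identity score."""

    read_id: str
    chromosome: str
    strand: str
    blocks: tuple[Interval, ...]
    identity: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        if not (0.0 <= self.identity <= 1.0):
            raise ValidationError(f"{self.read_id}: identity must be in [0,1]")
        # reuse transcript validation (sorted, disjoint, non-touching)
        TranscriptModel(self.read_id, self.chromosome, self.strand, self.blocks)

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    def junctions(self) -> JunctionChain:
        return TranscriptModel(
            self.read_id, self.chromosome, self.strand, self.blocks
        ).introns()


@dataclass
class IsoformRecord:
    """One catalog entry: a splice form with its evidence and labels."""

    isoform_id: str
    transcript: TranscriptModel
    support: int
    mean_identity: float
    gene_id: str = UNASSIGNED
    junction_verified: tuple[bool, ...] = ()
    novelty: str | None = None  # "annotated" | "novel"
    events: tuple = ()
    retained_domains: frozenset[str] = frozenset()

    @property
    def chain(self) -> JunctionChain:
        return self.transcript.introns()


# ---------------------------------------------------------------------------
# BED12-style I/O


def write_bed12(reads: Iterable[AlignedRead], path: str | Path) -> None:
    """Write reads as BED12 rows; the score column carries alignment
    identity as a fraction (6 decimals)."""
    lines = []
    for r in reads:
        start, end = r.span
        sizes = ",".join(str(e - s) for s, e in r.blocks)
        starts = ",".join(str(s - start) for s, _ in r.blocks)
        lines.append(
            "\t".join(
                [
                    r.chromosome,
                    str(start),
                    str(end),
                    r.read_id,
                    f"{r.identity:.6f}",
                    r.strand,
                    str(start),
                    str(end),
                    "0,0,0",
                    str(len(r.blocks)),
                    sizes,
                    starts,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed12(path: str | Path) -> list[AlignedRead]:
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValidationError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start = f[0], int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple(
                (start + o, start + o + sz) for o, sz in zip(offsets, sizes)
            )
            reads.append(
                AlignedRead(f[3], chrom, f[5], blocks, float(f[4]))
            )
    return reads


# ---------------------------------------------------------------------------
# collapse


def _cluster_mono(
    reads: Sequence[AlignedRead], tolerance: int
) -> list[list[AlignedRead]]:
    """Single-linkage clustering of mono-exonic reads: two reads link when
    they overlap and both their start and end positions agree within
    ``tolerance``."""
    order = sorted(reads, key=lambda r: (r.span, r.read_id))
    clusters: list[list[AlignedRead]] = []
    for r in order:
        merged_into: list[int] = []
        for k, cl in enumerate(clusters):
            for other in cl:
                a, b = r.span, other.span
                if (
                    a[0] < b[1]
                    and b[0] < a[1]
                    and abs(a[0] - b[0]) <= tolerance
                    and abs(a[1] - b[1]) <= tolerance
                ):
                    merged_into.append(k)
                    break
        if not merged_into:
            clusters.append([r])
        else:
            # single linkage: r may bridge several clusters
            target = merged_into[0]
            clusters[target].append(r)
            for k in reversed(merged_into[1:]):
                clusters[target].extend(clusters.pop(k))
    return clusters


def collapse_flnc(
    reads: Sequence[AlignedRead], mono_end_tolerance: int = 100
) -> list[IsoformRecord]:
    """Collapse FLNC reads into candidate isoforms.

    Multi-exonic reads are grouped by (chromosome, strand, junction chain);
    internal exon boundaries come from the shared junctions and terminal
    boundaries are the longest observed extents. Mono-exonic reads are
    grouped by single-linkage overlap within ``mono_end_tolerance``.
    Support is the member read count; mean identity is the member mean.
    """
    seen_ids: dict[str, str] = {}
    for r in reads:
        prev = seen_ids.get(r.read_id)
        if prev is not None and prev != r.chromosome:
            raise ValidationError(
                f"read id {r.read_id} appears on chromosomes {prev} and "
                f"{r.chromosome}"
            )
        seen_ids[r.read_id] = r.chromosome

    multi: dict[tuple, list[AlignedRead]] = {}
    mono: dict[tuple[str, str], list[AlignedRead]] = {}
    for r in reads:
        if len(r.blocks) == 1:
            mono.setdefault((r.chromosome, r.strand), []).append(r)
        else:
            key = (r.chromosome, r.strand, tuple(r.junctions()))
            multi.setdefault(key, []).append(r)

    groups: list[list[AlignedRead]] = []
    for key in sorted(multi, key=str):
        groups.append(multi[key])
    for key in sorted(mono):
        groups.extend(_cluster_mono(mono[key], mono_end_tolerance))

    candidates: list[IsoformRecord] = []
    for members in groups:
        chrom = members[0].chromosome
        strand = members[0].strand
        start = min(r.span[0] for r in members)
        end = max(r.span[1] for r in members)
        chain = members[0].junctions() if len(members[0].blocks) > 1 else JunctionChain(())
        tx = TranscriptModel.from_span_and_introns(
            "candidate", chrom, strand, (start, end), chain
        )
        candidates.append(
            IsoformRecord(
                isoform_id="candidate",
                transcript=tx,
                support=len(members),
                mean_identity=sum(r.identity for r in members) / len(members),
            )
        )
    candidates.sort(
        key=lambda c: (c.transcript.chromosome, c.transcript.span, tuple(c.chain))
    )
    for i, c in enumerate(candidates):
        iid = f"cand{i + 1:04d}"
        c.isoform_id = iid
        c.transcript = replace(c.transcript, transcript_id=iid)
    return candidates


# ---------------------------------------------------------------------------
# filtering


JunctionSupport = set[tuple[str, int, int]]


def read_junction_support(path: str | Path) -> JunctionSupport:
    """Read a ``chrom start end supported`` TSV into the supported set."""
    supported: JunctionSupport = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["chrom", "start", "end", "supported"]:
            raise ValidationError(f"{path}: unexpected junction header {header}")
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, ok = line.rstrip("\n").split("\t")
            if ok in ("1", "True", "true"):
                supported.add((chrom, int(s), int(e)))
    return supported


def _annotated_junctions(annotation: Sequence[GeneModel]) -> JunctionSupport:
    out: JunctionSupport = set()
    for g in annotation:
        for t in g.transcripts:
            for s, e in t.introns():
                out.add((g.chromosome, s, e))
    return out


def filter_catalog(
    candidates: Sequence[IsoformRecord],
    junction_support: JunctionSupport,
    annotation: Sequence[GeneModel],
    min_support: int = 2,
    min_identity: float = 0.90,
) -> list[IsoformRecord]:
    """Keep candidates with enough read support, high enough identity, and
    every junction verified by short reads or by the annotation.

    Mono-exonic candidates have no junctions to verify and pass on
    support + identity alone.
    """
    annotated = _annotated_junctions(annotation)
    kept: list[IsoformRecord] = []
    for c in candidates:
        if c.support < min_support or c.mean_identity < min_identity:
            continue
        chrom = c.transcript.chromosome
        flags = tuple(
            (chrom, s, e) in junction_support or (chrom, s, e) in annotated
            for s, e in c.chain
        )
        if all(flags):
            kept.append(replace_record(c, junction_verified=flags))
    return kept


def replace_record(rec: IsoformRecord, **kw) -> IsoformRecord:
    new = IsoformRecord(
        isoform_id=rec.isoform_id,
        transcript=rec.transcript,
        support=rec.support,
        mean_identity=rec.mean_identity,
        gene_id=rec.gene_id,
        junction_verified=rec.junction_verified,
        novelty=rec.novelty,
        events=rec.events,
        retained_domains=rec.retained_domains,
    )
    for k, v in kw.items():
        setattr(new, k, v)
    return new


# ---------------------------------------------------------------------------
# gene assignment + novelty


def _exonic_overlap(tx: TranscriptModel, gene: GeneModel) -> int:
    total = 0
    gene_exons = [e for t in gene.transcripts for e in t.exons]
    for s, e in tx.exons:
        for gs, ge in gene_exons:
            total += max(0, min(e, ge) - max(s, gs))
    return total


def assign_gene(
    tx: TranscriptModel, annotation: Sequence[GeneModel]
) -> str:
    """Assign a transcript to the same-strand gene with maximal exonic
    overlap; ties go to the larger overlap fraction of the transcript,
    then the lexicographically smaller gene id."""
    best: tuple[float, float, str] | None = None
    best_gene = UNASSIGNED
    for g in annotation:
        if g.chromosome != tx.chromosome or g.strand != tx.strand:
            continue
        if g.span[1] <= tx.span[0] or tx.span[1] <= g.span[0]:
            continue
        ov = _exonic_overlap(tx, g)
        if ov <= 0:
            continue
        key = (-ov, -ov / tx.spliced_length, g.gene_id)
        if best is None or key < best:
            best = key
            best_gene = g.gene_id
    return best_gene


def label_novelty(
    catalog: Sequence[IsoformRecord],
    annotation: Sequence[GeneModel],
    mono_end_tolerance: int = 100,
) -> tuple[list[IsoformRecord], dict[str, dict[str, int]]]:
    """Assign genes and label each catalog isoform annotated or novel.

    A multi-exonic isoform is annotated iff its junction chain is identical
    to some annotated transcript of its assigned gene; a mono-exonic one
    iff a mono-exonic annotated transcript matches its span within the end
    tolerance. Returns the labelled catalog and per-gene counts
    ``{gene_id: {"annotated": n, "novel": m}}``.
    """
    by_gene = {g.gene_id: g for g in annotation}
    labelled: list[IsoformRecord] = []
    counts: dict[str, dict[str, int]] = {}
    for rec in catalog:
        gid = assign_gene(rec.transcript, annotation)
        novelty = "novel"
        if gid != UNASSIGNED:
            gene = by_gene[gid]
            chain = tuple(rec.chain)
            for t in gene.transcripts:
                if chain:
                    if tuple(t.introns()) == chain:
                        novelty = "annotated"
                        break
                elif t.n_exons == 1:
                    a, b = rec.transcript.span, t.span
                    if (
                        abs(a[0] - b[0]) <= mono_end_tolerance
                        and abs(a[1] - b[1]) <= mono_end_tolerance
                    ):
                        novelty = "annotated"
                        break
        out = replace_record(rec, gene_id=gid, novelty=novelty)
        labelled.append(out)
        slot = counts.setdefault(gid, {"annotated": 0, "novel": 0})
        slot[novelty] += 1
    return labelled, counts


def write_catalog(catalog: Sequence[IsoformRecord], path: str | Path) -> None:
    lines = ["isoform_id\tgene_id\tsupport\tmean_identity\tnovelty\tn_exons"]
    for r in catalog:
        lines.append(
            f"{r.isoform_id}\t{r.gene_id}\t{r.support}\t"
            f"{r.mean_identity:.6f}\t{r.novelty}\t{r.transcript.n_exons}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
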