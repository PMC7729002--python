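"""Coordinate-aware gene and transcript models, annotation I/O, and the
two-domain gene-family membership filter.

All internal coordinates are 0-based half-open genomic intervals; GTF/GFF3
readers and writers convert at the boundary (1-based inclusive on disk).
Strand is stored, but exon and intron intervals are always kept in genome
orientation; transcription-direction logic lives in :mod:`homeosplice.events`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils

log = logging.getLogger(__name__)

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class AnnotationError(ValueError):
    """Base class for annotation parsing/validation problems."""


class AnnotationFormatError(AnnotationError):
    """A line of a GTF/GFF3 file could not be parsed."""


class ValidationError(AnnotationError):
    """Structurally invalid gene/transcript content."""


def _check_intervals(ivals: Sequence[Interval], what: str) -> None:
    for s, e in ivals:
        if not (0 <= s < e):
            raise ValidationError(f"{what}: invalid interval [{s},{e})")
    for (s0, e0), (s1, e1) in zip(ivals, ivals[1:]):
        if s1 < e0:
            raise ValidationError(f"{what}: intervals overlap or unsorted at [{s1},{e1})")
        if s1 == e0:
            raise ValidationError(
                f"{what}: adjacent intervals [{s0},{e0}) and [{s1},{e1}) "
                "touch; merge them upstream"
            )


@dataclass(frozen=True)
class JunctionChain:
    """Ordered intron intervals of a transcript, in genome orientation.

    Two multi-exonic transcripts with identical chains (and overlapping
    spans) are the same splice form; the chain is empty for mono-exonic
    transcripts.
    """

    introns: tuple[Interval, ...]

    def __post_init__(self) -> None:
        _check_intervals(self.introns, "junction chain")

    def __len__(self) -> int:
        return len(self.introns)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.introns)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered chain of disjoint exon intervals."""

    transcript_id: str
    chromosome: str
    strand: str
    exons: tuple[Interval, ...]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        if len(self.exons) < 1:
            raise ValidationError(f"{self.transcript_id}: needs at least one exon")
        object.__setattr__(self, "exons", tuple(tuple(x) for x in self.exons))
        _check_intervals(self.exons, self.transcript_id)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> JunctionChain:
        gaps = tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )
        return JunctionChain(gaps)

    @classmethod
    def from_span_and_introns(
        cls,
        transcript_id: str,
        chromosome: str,
        strand: str,
        span: Interval,
        chain: JunctionChain,
        gene_id: str | None = None,
    ) -> "TranscriptModel":
        """Reconstruct exons from a span plus an intron chain (the inverse
        of :func:`introns_of`)."""
        bounds = [span[0]]
        for s, e in chain:
            bounds.extend([s, e])
        bounds.append(span[1])
        exons = tuple((bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2))
        return cls(transcript_id, chromosome, strand, exons, gene_id=gene_id)


def introns_of(t: TranscriptModel) -> JunctionChain:
    """Gaps between consecutive exons, in genome orientation."""
    return t.introns()


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcripts and (optional) homeolog-triad metadata.

    ``subgenome`` identifies the ancestral genome of an allopolyploid the
    gene copy belongs to (wheat A, B or D); ``triad_id`` links the three
    homeologous copies, one per subgenome.
    """

    gene_id: str
    chromosome: str
    strand: str
    span: Interval
    transcripts: tuple[TranscriptModel, ...]
    subgenome: str = "other"
    subfamily: str | None = None
    triad_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        s, e = self.span
        if not (0 <= s < e):
            raise ValidationError(f"{self.gene_id}: invalid span [{s},{e})")
        for t in self.transcripts:
            if t.chromosome != self.chromosome or t.strand != self.strand:
                raise ValidationError(
                    f"transcript {t.transcript_id} disagrees with gene "
                    f"{self.gene_id} on chromosome/strand"
                )
            if t.span[0] < s or t.span[1] > e:
                raise ValidationError(
                    f"transcript {t.transcript_id} lies outside gene "
                    f"{self.gene_id} span"
                )

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


# ---------------------------------------------------------------------------
# sequence access


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Concatenated exon sequence in transcription order (5'->3' mRNA).

    ``genome`` maps chromosome name to its full sequence. Minus-strand
    transcripts are reverse-complemented.
    """
    if t.chromosome not in genome:
        raise KeyError(f"chromosome {t.chromosome!r} not in genome")
    chrom = str(genome[t.chromosome])
    if t.span[1] > len(chrom):
        raise ValidationError(
            f"{t.transcript_id}: exon end {t.span[1]} beyond chromosome "
            f"{t.chromosome} length {len(chrom)}"
        )
    seq = "".join(chrom[s:e] for s, e in t.exons).upper()
    return reverse_complement(seq) if t.strand == "-" else seq


# ---------------------------------------------------------------------------
# annotation I/O


def _prevalidate(path: Path) -> tuple[str, bool]:
    """Cheap syntactic pass: returns (dialect, has_explicit_parents).

    dialect is "gff3" when the attribute column uses ``key=value`` syntax,
    otherwise "gtf". Raises AnnotationFormatError with the offending line
    number on malformed rows.
    """
    dialect = None
    explicit = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: invalid 1-based coordinates {start}-{end}"
                )
            if dialect is None:
                attr = fields[8]
                dialect = "gff3" if ("=" in attr and '"' not in attr) else "gtf"
            if fields[2] in ("gene", "transcript", "mRNA"):
                explicit = True
    if dialect is None:
        raise AnnotationFormatError(f"{path}: no feature lines found")
    return dialect, explicit


def _attr(feature: gffutils.Feature, key: str) -> str | None:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read a GTF or GFF3 annotation into GeneModels.

    File coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention. Only ``gene``, ``transcript``/``mRNA``
    and ``exon`` features are consumed; other feature types are ignored.
    Output is deterministically ordered by (chromosome, start, gene_id).
    """
    path = Path(path)
    dialect, explicit = _prevalidate(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=explicit,
        disable_infer_transcripts=explicit,
    )

    tx_exons: dict[str, list[Interval]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    for ex in db.features_of_type("exon"):
        if dialect == "gtf":
            tid, gid = _attr(ex, "transcript_id"), _attr(ex, "gene_id")
        else:
            tid = _attr(ex, "Parent")
            gid = None
            if tid is not None:
                try:
                    parent = db[tid]
                    gid = _attr(parent, "Parent") or _attr(parent, "geneID")
                except gffutils.FeatureNotFoundError:
                    gid = None
        if tid is None:
            raise AnnotationFormatError(
                f"{path}: exon at {ex.seqid}:{ex.start}-{ex.end} lacks a "
                "transcript identifier"
            )
        if gid is None:
            gid = tid  # orphan transcript: gene named after it
        prev = tx_meta.get(tid)
        if prev is not None and prev[0] != gid:
            raise ValidationError(
                f"transcript {tid} appears under two genes: {prev[0]} and {gid}"
            )
        tx_meta[tid] = (gid, ex.seqid, ex.strand)
        tx_exons.setdefault(tid, []).append((ex.start - 1, ex.end))

    gene_meta: dict[str, gffutils.Feature] = {}
    for ftype in ("gene",):
        for g in db.features_of_type(ftype):
            gid = _attr(g, "gene_id") or _attr(g, "ID") or g.id
            gene_meta[gid] = g

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid in sorted(tx_exons):
        gid, chrom, strand = tx_meta[tid]
        exons = tuple(sorted(tx_exons[tid]))
        t = TranscriptModel(tid, chrom, strand, exons, gene_id=gid)
        by_gene.setdefault(gid, []).append(t)

    genes: list[GeneModel] = []
    for gid, txs in by_gene.items():
        txs.sort(key=lambda t: (t.span[0], t.transcript_id))
        chrom, strand = txs[0].chromosome, txs[0].strand
        lo = min(t.span[0] for t in txs)
        hi = max(t.span[1] for t in txs)
        meta = gene_meta.get(gid)
        if meta is not None:
            span = (meta.start - 1, meta.end)
            for t in txs:
                if t.span[0] < span[0] or t.span[1] > span[1]:
                    raise ValidationError(
                        f"transcript {t.transcript_id} extends outside the "
                        f"declared span of gene {gid}"
                    )
            subgenome = _attr(meta, "subgenome") or "other"
            subfamily = _attr(meta, "subfamily")
            triad_id = _attr(meta, "triad_id")
        else:
            span = (lo, hi)
            subgenome, subfamily, triad_id = "other", None, None
        genes.append(
            GeneModel(
                gene_id=gid,
                chromosome=chrom,
                strand=strand,
                span=span,
                transcripts=tuple(txs),
                subgenome=subgenome,
                subfamily=subfamily,
                triad_id=triad_id,
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.span[0], g.gene_id))
    return genes


def _gtf_attrs(pairs: Iterable[tuple[str, str | None]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs if v is not None)


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write GeneModels as normalized GTF (1-based inclusive coordinates)."""
    lines: list[str] = []
    for g in genes:
        gene_attrs = _gtf_attrs(
            [
                ("gene_id", g.gene_id),
                ("subgenome", g.subgenome),
                ("subfamily", g.subfamily),
                ("triad_id", g.triad_id),
            ]
        )
        lines.append(
            "\t".join(
                [
                    g.chromosome,
                    "homeosplice",
                    "gene",
                    str(g.span[0] + 1),
                    str(g.span[1]),
                    ".",
                    g.strand,
                    ".",
                    gene_attrs,
                ]
            )
        )
        for t in g.transcripts:
            tattrs = _gtf_attrs(
                [("gene_id", g.gene_id), ("transcript_id", t.transcript_id)]
            )
            lines.append(
                "\t".join(
                    [
                        g.chromosome,
                        "homeosplice",
                        "transcript",
                        str(t.span[0] + 1),
                        str(t.span[1]),
                        ".",
                        g.strand,
                        ".",
                        tattrs,
                    ]
                )
            )
            for s, e in t.exons:
                lines.append(
                    "\t".join(
                        [
                            g.chromosome,
                            "homeosplice",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            g.strand,
                            ".",
                            tattrs,
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def annotation_report(genes: Sequence[GeneModel]) -> dict:
    """Small JSON-able validation/summary report for an annotation set."""
    n_tx = sum(len(g.transcripts) for g in genes)
    exon_counts = {
        g.gene_id: [t.n_exons for t in g.transcripts] for g in genes
    }
    return {
        "n_genes": len(genes),
        "n_transcripts": n_tx,
        "chromosomes": sorted({g.chromosome for g in genes}),
        "exon_counts": exon_counts,
    }


# ---------------------------------------------------------------------------
# gene-family domain filter


@dataclass(frozen=True)
class DomainHit:
    """One sequence-search hit of a named protein domain on a candidate."""

    protein_id: str
    domain_name: str
    source: str  # "blast" or "hmmer"
    evalue: float
    identity: float | None = None  # percent; blast hits only

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.identity is not None and not (0 <= self.identity <= 100):
            raise ValueError("identity must be in [0, 100]")


def read_domain_hits(
    path: str | Path,
    max_evalue: float = 1e-5,
    min_identity: float = 50.0,
) -> list[DomainHit]:
    """Read a domain-hit TSV, applying the ingestion pre-filter.

    Hits with e-value above ``max_evalue``, or blast hits with identity at
    or below ``min_identity`` percent, are dropped (with a log line). The
    table header is ``protein_id domain_name source evalue identity``;
    identity may be empty/NA for hmmer hits.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein_id", "domain_name", "source", "evalue", "identity"]
        if header != expected:
            raise AnnotationFormatError(
                f"{path}: expected header {expected}, got {header}"
            )
        for line in fh:
            if not line.strip():
                continue
            pid, dom, src, ev, ident = line.rstrip("\n").split("\t")
            identity = None if ident in ("", "NA", ".") else float(ident)
            hit = DomainHit(pid, dom, src, float(ev), identity)
            if hit.evalue > max_evalue:
                log.debug("dropping %s/%s: evalue %g", pid, dom, hit.evalue)
                continue
            if hit.identity is not None and hit.identity <= min_identity:
                log.debug("dropping %s/%s: identity %.1f", pid, dom, hit.identity)
                continue
            hits.append(hit)
    return hits


def family_filter(
    hits: Iterable[DomainHit], required: set[str] | frozenset[str]
) -> set[str]:
    """Proteins carrying every required domain.

    Evidence from blast and hmmer is merged and de-duplicated: a (protein,
    domain) pair counts once no matter how many searches report it. A
    family defined by joint presence of an ATPase domain and a
    client-binding domain (e.g. HATPase_c + HSP90) is the motivating case.
    """
    if not required:
        raise ValueError("required domain set must be non-empty")
    seen: dict[str, set[str]] = {}
    for h in hits:
        seen.setdefault(h.protein_id, set()).add(h.domain_name)
    return {pid for pid, doms in seen.items() if set(required) <= doms}
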