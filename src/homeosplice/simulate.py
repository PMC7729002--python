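"""Synthetic-data generator with a known truth table for every stage.

The generator emulates the study system end to end: homeolog triads with
one gene copy per subgenome (A, B, D) and identical exon structure within
a triad; per-gene isoform sets carrying planted alternative-splicing
events; aligned full-length non-chimeric (FLNC) read records sampled from
the planted isoforms; a short-read junction-support table; and a heat
time-course isoform count matrix (negative binomial) with planted
fold-change and isoform-usage (IEP) shift effects.

Genes are built in transcript space from a restricted nucleotide alphabet
so that each coding region contains exactly two start codons — the true
start and an internal, in-frame start at the head of the last exon — and a
single in-frame stop. Each gene carries two labelled protein domains on
its canonical coding sequence: a 5'-biased domain (``NTD``) spanning the
first two exons and a 3'-biased domain (``CTD``) inside the last exon.
Under the default event plan the novel isoform of each homeolog therefore
retains only the 3' domain, mirroring truncated-peptide splice forms.

Reads are generated post-alignment (exon-chain records with identity
scores), not as raw sequences. All randomness derives from a single seed
through stage-keyed streams, so outputs are byte-identical across runs
and adding a stage never perturbs earlier ones.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .collapse import AlignedRead, write_bed12
from .events import ASEvent, DomainSpan, write_domain_spans
from .models import (
    GeneModel,
    TranscriptModel,
    reverse_complement,
    write_annotation,
)
from .quant import SampleDesign

_SAFE_CODONS = (
    "CTT", "GGT", "TCC", "GTC", "CCG", "TGC", "GCT", "TTC",
    "CGG", "GTG", "CCT", "TCG", "GGC", "TGT", "CTC", "GCC",
)
_SAFE_CHARS = "CGT"
_STAGE = {"structure": 1, "reads": 2, "counts": 3}

DOMAIN_5P = "NTD"
DOMAIN_3P = "CTD"


class SimulationConfigError(ValueError):
    """Invalid or structurally impossible simulation configuration."""


@dataclass(frozen=True)
class EventSpec:
    """A planted AS event: kind in {IR, ES, Alt5, Alt3}; ``index`` is the
    canonical intron (IR/Alt) or exon (ES) index, 1-based in transcription
    order; ``delta`` is the splice-site shift for Alt events."""

    kind: str
    index: int
    delta: int = 0


def _default_exon_counts() -> dict[str, int]:
    # one subfamily per triad, cycling; exon counts per subfamily mirror
    # the five wheat HSP90 subfamilies
    return {"AA": 3, "AB": 3, "B": 15, "C1": 19, "C2": 20}


@dataclass
class SimConfig:
    """All knobs of the generator; the defaults define the standard study
    conditions used by the recovery analyses.

    ``fractions`` are the planted molar isoform-usage percentages
    (canonical, novel-major, minor, rare) and ``shifted_fractions`` the
    redistributed usage at samples flagged for an IEP shift (a 40-point
    swing between the two major isoforms). ``nb_dispersion`` is the NB
    dispersion alpha in var = mu + alpha*mu^2; values at or below 1e-8
    switch to deterministic rounded means.
    """

    seed: int = 42
    n_triads: int = 5
    subfamilies: tuple[str, ...] = ("AA", "AB", "B", "C1", "C2")
    exon_counts: dict[str, int] = field(default_factory=_default_exon_counts)
    read_depth: float = 30.0
    read_identity: float = 1.0
    end_jitter: int = 50
    organs: tuple[str, ...] = ("G", "L")
    times: tuple[str, ...] = ("0m", "5m", "10m", "30m", "1h", "4h")
    nb_dispersion: float = 0.1
    baseline_mean: float = 2000.0
    library_size: float = 1e6  # total mapped fragments per sample (the
    # simulated gene panel is a small part of a whole transcriptome)
    fractions: tuple[float, ...] = (52.0, 35.0, 12.0, 1.0)
    shifted_fractions: tuple[float, ...] = (12.0, 75.0, 12.0, 1.0)
    de_fold_change: float = 4.0
    de_samples: tuple[str, ...] = ("G_10m", "G_30m", "L_10m")
    de_subgenomes: tuple[str, ...] = ("A", "D")
    as_shift_sample: str = "G_30m"
    as_shift_sample_alt: str = "L_1h"

    def design(self) -> SampleDesign:
        return SampleDesign(
            tuple((o, t) for o in self.organs for t in self.times)
        )

    def validate(self) -> None:
        if self.n_triads < 1:
            raise SimulationConfigError("n_triads must be >= 1")
        for sf in self.subfamilies:
            if self.exon_counts.get(sf, 0) < 3:
                raise SimulationConfigError(
                    f"subfamily {sf}: needs >= 3 exons for the default "
                    "event plan (internal exon + two introns)"
                )
        if "0m" not in self.times:
            raise SimulationConfigError("design lacks the 0m control time point")
        if abs(sum(self.fractions) - 100.0) > 1e-6:
            raise SimulationConfigError("fractions must sum to 100")
        if abs(sum(self.shifted_fractions) - 100.0) > 1e-6:
            raise SimulationConfigError("shifted_fractions must sum to 100")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STAGE[stage]])
        )


@dataclass
class TruthTable:
    """Planted ground truth for every downstream stage."""

    isoforms: dict[str, list[str]]  # gene -> isoform ids
    structures: dict[str, TranscriptModel]  # isoform id -> structure
    novelty: dict[str, str]  # isoform -> annotated|novel
    events: dict[str, tuple[ASEvent, ...]]  # isoform -> planted events
    classes: dict[str, str]  # isoform -> major|minor|rare
    fractions: dict[str, dict[str, float]]  # isoform -> sample -> planted IEP
    gene_fc: dict[str, dict[str, float]]  # gene -> sample -> planted FC
    de: dict[str, dict[str, bool]]  # gene -> sample -> DE planted
    diff_spliced: dict[str, dict[str, bool]]  # gene -> sample -> AS planted

    def to_json(self) -> str:
        payload = {
            "isoforms": self.isoforms,
            "novelty": self.novelty,
            "classes": self.classes,
            "events": {
                iso: [[e.type, e.index, e.delta_bp] for e in evs]
                for iso, evs in self.events.items()
            },
            "fractions": self.fractions,
            "gene_fc": self.gene_fc,
            "de": self.de,
            "diff_spliced": self.diff_spliced,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class Simulation:
    """In-memory bundle of everything the generator produced."""

    config: SimConfig
    genome: dict[str, str]
    annotation: list[GeneModel]  # canonical transcripts only
    isoform_annotation: list[GeneModel]  # all planted isoforms
    domains: dict[str, list[DomainSpan]]
    triad_map: pd.DataFrame  # triad_id gene_id subgenome subfamily
    truth: TruthTable

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gtf",
            "isoforms": outdir / "isoforms.gtf",
            "domains": outdir / "domains.tsv",
            "triads": outdir / "triads.tsv",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.genome, paths["genome"])
        write_annotation(self.annotation, paths["annotation"])
        write_annotation(self.isoform_annotation, paths["isoforms"])
        write_domain_spans(self.domains, paths["domains"])
        self.triad_map.to_csv(paths["triads"], sep="\t", index=False)
        paths["truth"].write_text(self.truth.to_json())
        return paths


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


# ---------------------------------------------------------------------------
# gene construction (transcript space)


def _safe_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_SAFE_CHARS), size=n))


@dataclass
class _GeneBlueprint:
    premrna: str  # 5'->3' pre-mRNA sequence
    exons_tx: list[tuple[int, int]]  # exon intervals in pre-mRNA coords
    restart_codon: int  # 1-based CDS codon index of the internal start
    n_cds_codons: int
    utr5: int
    domains: list[tuple[str, int, int]]  # (name, start_codon, end_codon) 0-based on ORF


def _build_blueprint(n_exons: int, rng: np.random.Generator) -> _GeneBlueprint:
    """Design one gene: exon codon layout, two planted domains, a single
    in-frame stop, and an internal restart ATG at the head of the last
    exon. Exon boundaries fall on codon boundaries."""
    if n_exons < 3:
        raise SimulationConfigError("genes need >= 3 exons")
    exon_codons = [28] + [12] * (n_exons - 2) + [36]
    n_codons = sum(exon_codons)
    restart = n_codons - 36 + 1  # first codon of the last exon (1-based)

    codons = [rng.choice(_SAFE_CODONS) for _ in range(n_codons)]
    codons[0] = "ATG"
    codons[restart - 1] = "ATG"
    codons[-1] = "TAA"
    cds = "".join(codons)

    utr5 = _safe_seq(rng, 12)
    utr3 = "CC" + _safe_seq(rng, 10)

    # exon segments of the mature mRNA (utr5 glued to exon 1, utr3 to last)
    segments: list[str] = []
    pos = 0
    for k, nc in enumerate(exon_codons):
        seg = cds[pos * 3 : (pos + nc) * 3]
        pos += nc
        if k == 0:
            seg = utr5 + seg
        if k == n_exons - 1:
            seg = seg + utr3
        segments.append(seg)

    intron_lengths = rng.integers(80, 121, size=n_exons - 1)
    premrna_parts: list[str] = []
    exons_tx: list[tuple[int, int]] = []
    cursor = 0
    for k, seg in enumerate(segments):
        exons_tx.append((cursor, cursor + len(seg)))
        premrna_parts.append(seg)
        cursor += len(seg)
        if k < n_exons - 1:
            ilen = int(intron_lengths[k])
            intron = "TAAC" + _safe_seq(rng, ilen - 4)
            premrna_parts.append(intron)
            cursor += ilen
    domains = [
        (DOMAIN_5P, 16, 36),  # codons 17..36, spanning exons 1-2
        (DOMAIN_3P, restart, restart + 20),  # 20 codons after the restart ATG
    ]
    return _GeneBlueprint(
        premrna="".join(premrna_parts),
        exons_tx=exons_tx,
        restart_codon=restart,
        n_cds_codons=n_codons,
        utr5=len(utr5),
        domains=domains,
    )


def _apply_events(
    exons_tx: Sequence[tuple[int, int]], events: Sequence[EventSpec]
) -> list[tuple[int, int]]:
    """Apply planted events to a transcript-space exon chain (transcription
    order, intron/exon indices 1-based)."""
    ex = [list(e) for e in exons_tx]
    n = len(ex)
    for ev in events:
        if ev.kind in ("Alt5", "Alt3"):
            if not (1 <= ev.index <= n - 1) or ev.delta <= 0:
                raise SimulationConfigError(f"invalid Alt spec {ev}")
            if ev.kind == "Alt5":
                ex[ev.index - 1][1] -= ev.delta  # donor moves into the exon
            else:
                ex[ev.index][0] += ev.delta  # acceptor moves into the exon
    removals = sorted(
        (ev for ev in events if ev.kind in ("IR", "ES")),
        key=lambda e: -e.index,
    )
    for ev in removals:
        if ev.kind == "IR":
            if not (1 <= ev.index <= len(ex) - 1):
                raise SimulationConfigError(f"invalid IR spec {ev}")
            ex[ev.index - 1][1] = ex[ev.index][1]
            del ex[ev.index]
        else:  # ES
            if not (2 <= ev.index <= len(ex) - 1):
                raise SimulationConfigError(
                    f"ES must target an internal exon: {ev}"
                )
            del ex[ev.index - 1]
    return [tuple(e) for e in ex]


def _tx_to_genomic(
    exons_tx: Sequence[tuple[int, int]], offset: int, length: int, strand: str
) -> tuple[tuple[int, int], ...]:
    if strand == "+":
        return tuple((offset + a, offset + b) for a, b in exons_tx)
    return tuple(
        sorted((offset + length - b, offset + length - a) for a, b in exons_tx)
    )


def _truth_events(
    blueprint: _GeneBlueprint, events: Sequence[EventSpec]
) -> tuple[ASEvent, ...]:
    exons = blueprint.exons_tx
    out = []
    for ev in events:
        if ev.kind == "IR":
            delta = exons[ev.index][0] - exons[ev.index - 1][1]
        elif ev.kind == "ES":
            a, b = exons[ev.index - 1]
            delta = b - a
        else:
            delta = ev.delta
        out.append(ASEvent(ev.kind, ev.index, delta))
    rank = {"IR": 0, "ES": 0, "Alt5": 0, "Alt3": 1}
    out.sort(key=lambda e: (e.index, rank[e.type]))
    return tuple(out)


def default_event_plan(subgenome: str, n_exons: int) -> dict[str, list[EventSpec]]:
    """The standard per-homeolog isoform plan.

    The novel major isoform differs by subgenome — Alt5+Alt3 on intron 1
    (A), intron-1 retention (B), exon-2 skipping (D) — mirroring the three
    distinct splicing modes observed within one homeolog triad. Every gene
    additionally gets a minor isoform (9-bp donor shift at the last
    intron) and a rare isoform (last-intron retention).
    """
    nimi = {
        "A": [EventSpec("Alt5", 1, 6), EventSpec("Alt3", 1, 6)],
        "B": [EventSpec("IR", 1)],
        "D": [EventSpec("ES", 2)],
    }[subgenome]
    last = n_exons - 1
    return {
        "nimi": nimi,
        "minor": [EventSpec("Alt5", last, 9)],
        "rare": [EventSpec("IR", last)],
    }


# ---------------------------------------------------------------------------
# triad simulation


def simulate_triads(cfg: SimConfig) -> Simulation:
    """Build the genome, annotation, planted isoforms and full truth table."""
    cfg.validate()
    rng = cfg.rng("structure")
    design = cfg.design()
    sample_ids = design.sample_ids

    genome_parts: dict[str, list[str]] = {f"chr{s}": [] for s in ("A", "B", "D")}
    cursors = {f"chr{s}": 0 for s in ("A", "B", "D")}

    annotation: list[GeneModel] = []
    iso_annotation: list[GeneModel] = []
    domains: dict[str, list[DomainSpan]] = {}
    triad_rows = []

    isoforms: dict[str, list[str]] = {}
    structures: dict[str, TranscriptModel] = {}
    novelty: dict[str, str] = {}
    events_truth: dict[str, tuple[ASEvent, ...]] = {}
    fractions: dict[str, dict[str, float]] = {}
    classes: dict[str, str] = {}
    gene_fc: dict[str, dict[str, float]] = {}
    de_truth: dict[str, dict[str, bool]] = {}
    as_truth: dict[str, dict[str, bool]] = {}

    for tr in range(cfg.n_triads):
        subfamily = cfg.subfamilies[tr % len(cfg.subfamilies)]
        n_exons = cfg.exon_counts[subfamily]
        triad_id = f"triad{tr + 1:02d}"
        for subgenome in ("A", "B", "D"):
            chrom = f"chr{subgenome}"
            strand = "-" if subgenome == "B" else "+"
            gene_id = f"t{tr + 1:02d}{subfamily}_{subgenome}"
            blueprint = _build_blueprint(n_exons, rng)

            spacer = _safe_seq(rng, 300)
            genome_parts[chrom].append(spacer)
            offset = cursors[chrom] + len(spacer)
            seg = (
                blueprint.premrna
                if strand == "+"
                else reverse_complement(blueprint.premrna)
            )
            genome_parts[chrom].append(seg)
            cursors[chrom] = offset + len(seg)
            glen = len(blueprint.premrna)

            plan = default_event_plan(subgenome, n_exons)
            iso_specs = [
                (f"{gene_id}.1", [], "annotated"),
                (f"{gene_id}.nimi", plan["nimi"], "novel"),
                (f"{gene_id}.min", plan["minor"], "novel"),
                (f"{gene_id}.rare", plan["rare"], "novel"),
            ]
            tx_models = []
            for iso_id, evs, nov in iso_specs:
                exons_tx = _apply_events(blueprint.exons_tx, evs)
                exons = _tx_to_genomic(exons_tx, offset, glen, strand)
                tx = TranscriptModel(iso_id, chrom, strand, exons, gene_id=gene_id)
                tx_models.append(tx)
                structures[iso_id] = tx
                novelty[iso_id] = nov
                events_truth[iso_id] = _truth_events(blueprint, evs)
            isoforms[gene_id] = [i for i, _, _ in iso_specs]

            gene_span = (offset, offset + glen)
            annotation.append(
                GeneModel(
                    gene_id,
                    chrom,
                    strand,
                    gene_span,
                    (tx_models[0],),
                    subgenome=subgenome,
                    subfamily=subfamily,
                    triad_id=triad_id,
                )
            )
            iso_annotation.append(
                GeneModel(
                    gene_id,
                    chrom,
                    strand,
                    gene_span,
                    tuple(tx_models),
                    subgenome=subgenome,
                    subfamily=subfamily,
                    triad_id=triad_id,
                )
            )
            domains[gene_id] = [
                DomainSpan(gene_id, name, s, e) for name, s, e in blueprint.domains
            ]
            triad_rows.append((triad_id, gene_id, subgenome, subfamily))

            # planted expression program -------------------------------
            shift_sample = None
            if tr % 2 == 0:
                shift_sample = cfg.as_shift_sample
            elif subgenome == "A":
                shift_sample = cfg.as_shift_sample
            elif subgenome == "B":
                shift_sample = cfg.as_shift_sample_alt
            gene_fc[gene_id] = {}
            de_truth[gene_id] = {}
            as_truth[gene_id] = {}
            for iso_id in isoforms[gene_id]:
                fractions[iso_id] = {}
            for sample in sample_ids:
                fc = (
                    cfg.de_fold_change
                    if subgenome in cfg.de_subgenomes and sample in cfg.de_samples
                    else 1.0
                )
                gene_fc[gene_id][sample] = fc
                de_truth[gene_id][sample] = fc >= 2.0 or (fc > 0 and fc <= 0.5)
                fr = (
                    cfg.shifted_fractions
                    if sample == shift_sample
                    else cfg.fractions
                )
                for iso_id, f in zip(isoforms[gene_id], fr):
                    fractions[iso_id][sample] = float(f)
            for sample in sample_ids:
                ctrl = design.control_of(sample)
                max_delta = max(
                    abs(fractions[i][sample] - fractions[i][ctrl])
                    for i in isoforms[gene_id]
                )
                as_truth[gene_id][sample] = (not design.is_control(sample)) and (
                    max_delta > 30.0
                )

    genome = {c: "".join(parts) + "C" * 50 for c, parts in genome_parts.items()}
    for iso_id, frac in fractions.items():
        classes[iso_id] = _planted_class(frac, design)

    truth = TruthTable(
        isoforms=isoforms,
        structures=structures,
        novelty=novelty,
        events=events_truth,
        classes=classes,
        fractions=fractions,
        gene_fc=gene_fc,
        de=de_truth,
        diff_spliced=as_truth,
    )
    annotation.sort(key=lambda g: (g.chromosome, g.span[0], g.gene_id))
    iso_annotation.sort(key=lambda g: (g.chromosome, g.span[0], g.gene_id))
    return Simulation(
        config=cfg,
        genome=genome,
        annotation=annotation,
        isoform_annotation=iso_annotation,
        domains=domains,
        triad_map=pd.DataFrame(
            triad_rows, columns=["triad_id", "gene_id", "subgenome", "subfamily"]
        ),
        truth=truth,
    )


def _planted_class(frac: Mapping[str, float], design: SampleDesign) -> str:
    """Apply the major/minor/rare rule to noise-free planted usage."""
    organ_means = []
    for organ in design.organs:
        cols = design.samples_of(organ)
        organ_means.append(sum(frac[s] for s in cols) / len(cols))
    if any(m > 30.0 for m in organ_means):
        return "major"
    if all(v < 5.0 for v in frac.values()):
        return "rare"
    return "minor"


# ---------------------------------------------------------------------------
# FLNC read simulation


def simulate_flnc(sim: Simulation, cfg: SimConfig | None = None) -> list[AlignedRead]:
    """Sample aligned FLNC reads from the planted isoforms.

    Read count per isoform is Poisson(read_depth); terminal exon ends are
    jittered inward by up to ``end_jitter`` bp (junctions never move at
    identity 1); with identity below 1 a matching fraction of reads gets
    one junction boundary perturbed, emulating residual alignment error.
    """
    cfg = cfg or sim.config
    rng = cfg.rng("reads")
    reads: list[AlignedRead] = []
    for iso_id in sorted(sim.truth.structures):
        tx = sim.truth.structures[iso_id]
        n = int(rng.poisson(cfg.read_depth))
        for k in range(n):
            blocks = [list(b) for b in tx.exons]
            if cfg.end_jitter > 0:
                first_len = blocks[0][1] - blocks[0][0]
                last_len = blocks[-1][1] - blocks[-1][0]
                blocks[0][0] += int(
                    rng.integers(0, min(cfg.end_jitter, first_len - 1) + 1)
                )
                blocks[-1][1] -= int(
                    rng.integers(0, min(cfg.end_jitter, last_len - 1) + 1)
                )
            identity = 1.0
            if cfg.read_identity < 1.0:
                identity = float(
                    np.clip(rng.normal(cfg.read_identity, 0.01), 0.0, 1.0)
                )
                if len(blocks) > 1 and rng.random() < (1.0 - cfg.read_identity):
                    j = int(rng.integers(0, len(blocks) - 1))
                    shift = int(rng.choice([-3, 3]))
                    if blocks[j][1] + shift > blocks[j][0] + 1 and (
                        blocks[j][1] + shift < blocks[j + 1][0]
                    ):
                        blocks[j][1] += shift
            reads.append(
                AlignedRead(
                    f"{iso_id}_r{k + 1}",
                    tx.chromosome,
                    tx.strand,
                    tuple(tuple(b) for b in blocks),
                    identity,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# count simulation


def simulate_counts(
    sim: Simulation, cfg: SimConfig | None = None
) -> tuple[pd.DataFrame, SampleDesign, pd.DataFrame]:
    """Negative-binomial isoform counts plus design and junction support.

    Per gene and sample, the mean total count is ``baseline_mean`` times
    the planted fold change; the gene mean is split among isoforms
    proportionally to planted usage times spliced length, so that the
    planted usage percentages are recovered exactly on the FPKM scale.
    The junction-support table marks every planted junction as short-read
    supported.
    """
    cfg = cfg or sim.config
    rng = cfg.rng("counts")
    design = cfg.design()
    truth = sim.truth
    sample_ids = design.sample_ids
    iso_ids = sorted(truth.structures)
    lengths = {i: truth.structures[i].spliced_length for i in iso_ids}

    deterministic = cfg.nb_dispersion <= 1e-8
    data = np.zeros((len(iso_ids), len(sample_ids)), dtype=int)
    iso_index = {i: k for k, i in enumerate(iso_ids)}
    for gene_id in sorted(truth.isoforms):
        members = truth.isoforms[gene_id]
        for s_idx, sample in enumerate(sample_ids):
            gene_mean = cfg.baseline_mean * truth.gene_fc[gene_id][sample]
            weights = np.array(
                [truth.fractions[i][sample] * lengths[i] for i in members]
            )
            means = gene_mean * weights / weights.sum()
            for iso_id, mu in zip(members, means):
                if mu <= 0:
                    val = 0
                elif deterministic:
                    val = int(round(mu))
                else:
                    r = 1.0 / cfg.nb_dispersion
                    val = int(rng.negative_binomial(r, r / (r + mu)))
                data[iso_index[iso_id], s_idx] = val
    counts = pd.DataFrame(data, index=iso_ids, columns=sample_ids)

    junctions = set()
    for tx in truth.structures.values():
        for s, e in tx.introns():
            junctions.add((tx.chromosome, s, e))
    support = pd.DataFrame(
        sorted(junctions), columns=["chrom", "start", "end"]
    ).assign(supported=1)
    return counts, design, support


def library_sizes(cfg: SimConfig) -> pd.Series:
    """Per-sample total mapped fragments (constant across the design)."""
    design = cfg.design()
    return pd.Series(cfg.library_size, index=design.sample_ids, name="library_size")


def simulate_all(
    cfg: SimConfig,
) -> tuple[Simulation, list[AlignedRead], pd.DataFrame, SampleDesign, pd.DataFrame]:
    """Convenience wrapper running all three generators with one config."""
    sim = simulate_triads(cfg)
    reads = simulate_flnc(sim)
    counts, design, support = simulate_counts(sim)
    return sim, reads, counts, design, support


def write_simulation(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full generator and write every output file."""
    outdir = Path(outdir)
    sim, reads, counts, design, support = simulate_all(cfg)
    paths = sim.write(outdir)
    paths["reads"] = outdir / "reads.bed"
    write_bed12(reads, paths["reads"])
    paths["counts"] = outdir / "counts.tsv"
    counts.to_csv(paths["counts"], sep="\t", index_label="isoform_id")
    paths["design"] = outdir / "design.tsv"
    design.to_frame().to_csv(paths["design"], sep="\t", index=False)
    paths["junctions"] = outdir / "junctions.tsv"
    support.to_csv(paths["junctions"], sep="\t", index=False)
    paths["library_sizes"] = outdir / "library_sizes.tsv"
    library_sizes(cfg).to_csv(paths["library_sizes"], sep="\t", index_label="sample_id")
    return paths
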