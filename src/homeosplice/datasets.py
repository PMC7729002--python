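"""Packaged reference fixtures.

Two small fixtures ship with the package:

* ``tahsp90_summary.tsv`` — the published per-gene summary of the 18
  hexaploid-wheat HSP90 genes (gene id, subfamily, subgenome, chromosome
  group, exon number, isoform number) used by the family summary report.
* the AA-subfamily demo triad — a synthetic reconstruction of the three
  AA-subfamily homeologs and their novel major isoforms: the A copy's
  novel isoform uses alternative 5' and 3' splice sites on intron 1, the B
  copy's retains intron 1, and the D copy's skips exon 2. The sequences
  are synthetic (built by the generator's gene designer, not the wheat
  genome); only the splice structures and the two-domain layout —
  an N-terminal HATPase_c domain spanning exons 1-2 and a C-terminal
  HSP90 domain in the last exon — reproduce the reported biology.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .events import DomainSpan
from .models import GeneModel, TranscriptModel
from .simulate import EventSpec, _apply_events, _build_blueprint

AA_TRIAD_DOMAIN_5P = "HATPase_c"
AA_TRIAD_DOMAIN_3P = "HSP90"

_AA_EVENTS = {
    "A": [EventSpec("Alt5", 1, 6), EventSpec("Alt3", 1, 6)],
    "B": [EventSpec("IR", 1)],
    "D": [EventSpec("ES", 2)],
}


def _data_path(name: str) -> Path:
    return Path(resources.files("homeosplice.data") / name)


def load_family_summary() -> pd.DataFrame:
    """The per-gene summary table of the 18 wheat HSP90s."""
    df = pd.read_csv(_data_path("tahsp90_summary.tsv"), sep="\t")
    expected = [
        "gene", "gene_id", "subfamily", "subgenome",
        "chromosome_group", "exon_number", "isoform_number",
    ]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected summary columns: {list(df.columns)}")
    return df


def build_aa_triad() -> tuple[
    list[GeneModel], dict[str, str], dict[str, list[DomainSpan]]
]:
    """Construct the synthetic AA-subfamily demo triad in memory.

    Returns (genes, genome, domains). Each gene has two transcripts: the
    canonical 3-exon form and the novel major isoform carrying that
    homeolog's splicing mode. Deterministic: the gene designer runs with a
    fixed internal seed.
    """
    rng = np.random.default_rng(20201127)
    genes: list[GeneModel] = []
    genome: dict[str, str] = {}
    domains: dict[str, list[DomainSpan]] = {}
    for sub in ("A", "B", "D"):
        bp = _build_blueprint(3, rng)
        gene_id = f"TaHSP90AA-2{sub}"
        chrom = f"chr2{sub}"
        offset = 100
        genome[chrom] = "C" * offset + bp.premrna + "C" * 100
        txs = []
        for suffix, evs in (("1", []), ("nimi", _AA_EVENTS[sub])):
            exons_tx = _apply_events(bp.exons_tx, evs)
            exons = tuple((offset + a, offset + b) for a, b in exons_tx)
            txs.append(
                TranscriptModel(
                    f"{gene_id}.{suffix}", chrom, "+", exons, gene_id=gene_id
                )
            )
        genes.append(
            GeneModel(
                gene_id,
                chrom,
                "+",
                (offset, offset + len(bp.premrna)),
                tuple(txs),
                subgenome=sub,
                subfamily="AA",
                triad_id="AA-2",
            )
        )
        domains[gene_id] = [
            DomainSpan(gene_id, AA_TRIAD_DOMAIN_5P, bp.domains[0][1], bp.domains[0][2]),
            DomainSpan(gene_id, AA_TRIAD_DOMAIN_3P, bp.domains[1][1], bp.domains[1][2]),
        ]
    return genes, genome, domains


def load_aa_triad() -> tuple[
    list[GeneModel], dict[str, str], dict[str, list[DomainSpan]]
]:
    """Load the packaged AA demo triad (GTF + FASTA + domain TSV)."""
    from .events import read_domain_spans
    from .models import read_annotation
    from .simulate import read_fasta

    genes = read_annotation(_data_path("aa_triad.gtf"))
    genome = read_fasta(_data_path("aa_triad_genome.fa"))
    domains = read_domain_spans(_data_path("aa_triad_domains.tsv"))
    return genes, genome, domains


def export_aa_triad(outdir: str | Path) -> dict[str, Path]:
    """Write the in-memory demo triad as GTF/FASTA/TSV files."""
    from .events import write_domain_spans
    from .models import write_annotation
    from .simulate import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, genome, domains = build_aa_triad()
    paths = {
        "gtf": outdir / "aa_triad.gtf",
        "fasta": outdir / "aa_triad_genome.fa",
        "domains": outdir / "aa_triad_domains.tsv",
    }
    write_annotation(genes, paths["gtf"])
    write_fasta(genome, paths["fasta"])
    write_domain_spans(domains, paths["domains"])
    return paths
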