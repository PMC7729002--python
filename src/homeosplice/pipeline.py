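"""End-to-end orchestration: inputs (or simulation) through catalog,
events, quantification, response calling and triad reports, with a run
manifest, plus the packaged family summary report.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import collapse as clp
from . import datasets, events as evm, quant, response as rsp, triads as trd
from .models import GeneModel, TranscriptModel, read_annotation
from .quant import SampleDesign
from .simulate import (
    SimConfig,
    Simulation,
    read_fasta,
    simulate_counts,
    simulate_flnc,
    simulate_triads,
)

log = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulate`` (a SimConfig) or ``inputs`` (a mapping of
    input-file paths with keys annotation, genome, reads, junctions,
    counts, design, domains, triads, isoforms) must be given. Threshold
    defaults follow the published analysis: DE requires fold change >= 2
    at FDR < 0.01; major/rare isoform IEP cutoffs 30/5; a differential-
    splicing IEP shift must exceed 30 points; the expressed-set FPKM
    cutoff is 1.
    """

    outdir: str | Path = "homeosplice_run"
    seed: int = 42
    simulate: SimConfig | None = None
    inputs: dict[str, str] | None = None
    min_support: int = 2
    min_identity: float = 0.90
    mono_end_tolerance: int = 100
    min_orf_codons: int = 30
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.01
    dispersion: float = 0.1
    iep_major: float = 30.0
    iep_rare: float = 5.0
    iep_shift: float = 30.0
    fpkm_expressed: float = 1.0

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise PipelineConfigError(
                "exactly one of 'simulate' or 'inputs' must be configured"
            )
        for name in (
            "min_support", "fc_threshold", "fdr_threshold", "iep_major",
            "iep_rare", "iep_shift", "fpkm_expressed", "min_identity",
        ):
            if getattr(self, name) <= 0:
                raise PipelineConfigError(f"threshold {name} must be positive")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _chain_key(tx: TranscriptModel) -> tuple:
    return (tx.chromosome, tx.strand, tuple(tx.introns()))


def match_counts_to_catalog(
    catalog: Sequence[clp.IsoformRecord],
    iso_annotation: Sequence[GeneModel],
    counts: pd.DataFrame,
    mono_end_tolerance: int = 100,
) -> pd.DataFrame:
    """Re-key a quantified count matrix onto catalog isoform ids.

    Quantified transcripts (rows of ``counts``, structures in
    ``iso_annotation``) are matched to catalog isoforms by junction-chain
    identity (mono-exonic: span agreement within the end tolerance).
    Catalog isoforms without a quantified counterpart get zero counts;
    unmatched count rows are dropped with a log line.
    """
    by_chain: dict[tuple, str] = {}
    mono: list[TranscriptModel] = []
    for g in iso_annotation:
        for t in g.transcripts:
            if t.n_exons > 1:
                by_chain[_chain_key(t)] = t.transcript_id
            else:
                mono.append(t)
    matched: dict[str, str] = {}
    for rec in catalog:
        tx = rec.transcript
        if tx.n_exons > 1:
            src = by_chain.get(_chain_key(tx))
        else:
            src = None
            for t in mono:
                if (
                    t.chromosome == tx.chromosome
                    and t.strand == tx.strand
                    and abs(t.span[0] - tx.span[0]) <= mono_end_tolerance
                    and abs(t.span[1] - tx.span[1]) <= mono_end_tolerance
                ):
                    src = t.transcript_id
                    break
        if src is not None and src in counts.index:
            matched[rec.isoform_id] = src
    out = pd.DataFrame(
        0, index=[r.isoform_id for r in catalog], columns=counts.columns, dtype=int
    )
    for iso_id, src in matched.items():
        out.loc[iso_id] = counts.loc[src].astype(int)
    unmatched = set(counts.index) - set(matched.values())
    if unmatched:
        log.info("%d quantified transcripts not in catalog", len(unmatched))
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order, write all intermediates, and return
    the run manifest (also written as ``manifest.json``)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "thresholds": {
            k: getattr(cfg, k)
            for k in (
                "min_support", "min_identity", "fc_threshold", "fdr_threshold",
                "iep_major", "iep_rare", "iep_shift", "fpkm_expressed",
                "dispersion", "min_orf_codons", "mono_end_tolerance",
            )
        },
        "stages": {},
        "files": {},
    }

    # ---- stage: inputs ---------------------------------------------------
    try:
        if cfg.simulate is not None:
            simcfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
            sim = simulate_triads(simcfg)
            reads = simulate_flnc(sim)
            counts_src, design, support_df = simulate_counts(sim)
            from .simulate import library_sizes as _sim_libs
            lib_sizes = _sim_libs(simcfg)
            annotation = sim.annotation
            genome = sim.genome
            iso_annotation = sim.isoform_annotation
            domains = sim.domains
            triad_map = sim.triad_map
            indir = outdir / "inputs"
            indir.mkdir(exist_ok=True)
            sim.write(indir)
            clp.write_bed12(reads, indir / "reads.bed")
            counts_src.to_csv(indir / "counts.tsv", sep="\t", index_label="isoform_id")
            design.to_frame().to_csv(indir / "design.tsv", sep="\t", index=False)
            support_df.to_csv(indir / "junctions.tsv", sep="\t", index=False)
            lib_sizes.to_csv(indir / "library_sizes.tsv", sep="\t", index_label="sample_id")
        else:
            paths = {k: Path(v) for k, v in cfg.inputs.items()}
            sim = None
            annotation = read_annotation(paths["annotation"])
            genome = read_fasta(paths["genome"])
            reads = clp.read_bed12(paths["reads"])
            support_df = pd.read_csv(paths["junctions"], sep="\t")
            counts_src = pd.read_csv(paths["counts"], sep="\t", index_col=0)
            design = SampleDesign.read_tsv(paths["design"])
            domains = evm.read_domain_spans(paths["domains"])
            triad_map = pd.read_csv(paths["triads"], sep="\t")
            iso_annotation = (
                read_annotation(paths["isoforms"]) if "isoforms" in paths else annotation
            )
            if "library_sizes" in paths:
                lib_sizes = pd.read_csv(
                    paths["library_sizes"], sep="\t", index_col=0
                ).iloc[:, 0]
            else:
                lib_sizes = counts_src.sum(axis=0)
        support = {
            (r.chrom, int(r.start), int(r.end))
            for r in support_df.itertuples()
            if int(r.supported) == 1
        }
        manifest["stages"]["inputs"] = {
            "n_genes": len(annotation),
            "n_reads": len(reads),
            "n_supported_junctions": len(support),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    # ---- stage: collapse -------------------------------------------------
    try:
        candidates = clp.collapse_flnc(reads, cfg.mono_end_tolerance)
        filtered = clp.filter_catalog(
            candidates, support, annotation, cfg.min_support, cfg.min_identity
        )
        catalog, novelty_counts = clp.label_novelty(
            filtered, annotation, cfg.mono_end_tolerance
        )
        clp.write_catalog(catalog, outdir / "catalog.tsv")
        _write_catalog_gtf(catalog, outdir / "catalog.gtf")
        manifest["stages"]["collapse"] = {
            "n_candidates": len(candidates),
            "n_filtered_out": len(candidates) - len(filtered),
            "n_catalog": len(catalog),
            "novelty": {
                k: dict(v) for k, v in sorted(novelty_counts.items())
            },
        }
        log.info(
            "collapse: %d reads -> %d candidates -> %d kept",
            len(reads), len(candidates), len(catalog),
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'collapse' failed: {exc}") from exc

    # ---- stage: events ---------------------------------------------------
    try:
        gene_by_id = {g.gene_id: g for g in annotation}
        canonical: dict[str, TranscriptModel] = {
            gid: evm.canonical_isoform(g, genome, cfg.min_orf_codons)
            for gid, g in gene_by_id.items()
        }
        ev_rows, dom_rows = [], []
        for rec in catalog:
            if rec.gene_id == clp.UNASSIGNED:
                continue
            can = canonical[rec.gene_id]
            evs = evm.classify_events(rec.transcript, can)
            rec.events = tuple(evs)
            for e in evs:
                ev_rows.append(
                    (rec.isoform_id, rec.gene_id, e.type, e.index, e.delta_bp)
                )
            retained = evm.domain_retention(
                rec.transcript,
                can,
                domains.get(rec.gene_id, []),
                genome,
                cfg.min_orf_codons,
            )
            rec.retained_domains = frozenset(retained)
            dom_rows.append((rec.isoform_id, ";".join(sorted(retained))))
        events_df = pd.DataFrame(
            ev_rows,
            columns=["isoform_id", "gene_id", "event_type", "index", "delta_bp"],
        )
        events_df.to_csv(outdir / "events.tsv", sep="\t", index=False)
        pd.DataFrame(dom_rows, columns=["isoform_id", "retained_domains"]).to_csv(
            outdir / "domains_retained.tsv", sep="\t", index=False
        )
        manifest["stages"]["events"] = {
            "n_events": len(events_df),
            "by_type": events_df["event_type"].value_counts().to_dict()
            if len(events_df)
            else {},
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'events' failed: {exc}") from exc

    quant_possible = counts_src is not None and len(counts_src) > 0
    if not quant_possible:
        log.info("no expression data: quant/response stages skipped")
        manifest["stages"]["quant"] = {"skipped": True}
        manifest["stages"]["response"] = {"skipped": True}

    # ---- stage: quant ----------------------------------------------------
    classes_df = response_df = top_df = None
    if quant_possible:
        try:
            counts = match_counts_to_catalog(
                catalog, iso_annotation, counts_src, cfg.mono_end_tolerance
            )
            assigned = [r.isoform_id for r in catalog if r.gene_id != clp.UNASSIGNED]
            counts = counts.loc[assigned]
            gene_map = pd.Series(
                {r.isoform_id: r.gene_id for r in catalog}
            ).loc[assigned]
            lengths = pd.Series(
                {r.isoform_id: r.transcript.spliced_length for r in catalog}
            ).loc[assigned]
            fpkm_df = quant.fpkm(counts, lengths, lib_sizes)
            iep_df = quant.iep(fpkm_df, gene_map)
            classes_df = quant.classify_abundance(
                iep_df, design, cfg.iep_major, cfg.iep_rare
            )
            classes_df = classes_df.assign(
                gene_id=gene_map,
                novelty=pd.Series({r.isoform_id: r.novelty for r in catalog}),
            )
            classes_df.index.name = "isoform_id"
            top_df = quant.most_abundant(fpkm_df, gene_map)
            fpkm_df.to_csv(outdir / "fpkm.tsv", sep="\t", index_label="isoform_id")
            iep_df.to_csv(outdir / "iep.tsv", sep="\t", index_label="isoform_id")
            classes_df.to_csv(outdir / "classes.tsv", sep="\t")
            top_df.to_csv(outdir / "most_abundant.tsv", sep="\t", index=False)
            manifest["stages"]["quant"] = {
                "n_isoforms": int(len(counts)),
                "classes": classes_df["class"].value_counts().to_dict(),
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'quant' failed: {exc}") from exc

        # ---- stage: response --------------------------------------------
        try:
            junction_ok = {
                r.isoform_id: bool(all(r.junction_verified))
                for r in catalog
                if r.gene_id != clp.UNASSIGNED
            }
            response_df = rsp.build_response_table(
                counts,
                fpkm_df,
                iep_df,
                gene_map,
                design,
                junction_ok,
                cfg.fc_threshold,
                cfg.fdr_threshold,
                cfg.dispersion,
                cfg.iep_shift,
                cfg.fpkm_expressed,
                library_sizes=lib_sizes,
            )
            response_df.to_csv(outdir / "response.tsv", sep="\t", index=False)
            rsp.response_matrix(response_df).to_csv(
                outdir / "response_matrix.tsv", sep="\t"
            )
            manifest["stages"]["response"] = {
                "n_tr_de": int(response_df["tr_de"].sum()),
                "n_as_diff": int(response_df["as_diff"].sum()),
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'response' failed: {exc}") from exc

    # ---- stage: triads ---------------------------------------------------
    try:
        exon_counts = {gid: canonical[gid].n_exons for gid in canonical}
        if classes_df is not None:
            cls_for_triads = classes_df.reset_index()[
                ["isoform_id", "gene_id", "class", "novelty"]
            ]
        else:
            cls_for_triads = pd.DataFrame(
                columns=["isoform_id", "gene_id", "class", "novelty"]
            )
        ev_for_triads = (
            events_df[["isoform_id", "event_type"]]
            if len(events_df)
            else pd.DataFrame(columns=["isoform_id", "event_type"])
        )
        reports = []
        for triad_id, sub in triad_map.groupby("triad_id"):
            reports.append(
                trd.build_triad_report(
                    triad_id,
                    sub,
                    exon_counts,
                    cls_for_triads,
                    ev_for_triads,
                    response_df,
                    top_df,
                )
            )
        summary = trd.triad_summary(reports)
        summary.to_csv(outdir / "triad_summary.tsv", sep="\t", index=False)
        manifest["stages"]["triads"] = {
            "n_triads": len(reports),
            "n_structure_conserved": int(
                sum(1 for r in reports if r.structure_conserved)
            ),
            "n_nimi_divergent": int(
                sum(1 for r in reports if r.nimi_modes_divergent)
            ),
            "n_as_discordant": int(
                sum(1 for r in reports if r.as_response_concordant is False)
            ),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'triads' failed: {exc}") from exc

    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(outdir))] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# truth-recovery metrics


def _write_catalog_gtf(catalog: Sequence[clp.IsoformRecord], path: Path) -> None:
    lines = []
    for rec in catalog:
        tx = rec.transcript
        attrs = f'gene_id "{rec.gene_id}"; transcript_id "{rec.isoform_id}";'
        rows = [("transcript", tx.span)] + [("exon", e) for e in tx.exons]
        for ftype, (s, e) in rows:
            lines.append(
                "\t".join(
                    [
                        tx.chromosome, "homeosplice", ftype,
                        str(s + 1), str(e), ".", tx.strand, ".", attrs,
                    ]
                )
            )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def recovery_metrics(
    sim: Simulation,
    outdir: str | Path,
    catalog: Sequence[clp.IsoformRecord] | None = None,
) -> dict:
    """Compare a pipeline run against the generator's planted truth.

    Reads the run outputs in ``outdir`` (catalog/events/classes/response
    TSVs) and reports catalog precision/recall on junction chains plus
    exact-recovery fractions for event sets, abundance classes,
    differential-splicing flags and transcriptional DE flags.
    """
    outdir = Path(outdir)
    truth = sim.truth
    truth_by_chain = {
        _chain_key(tx): iso_id for iso_id, tx in truth.structures.items()
    }

    cat = pd.read_csv(outdir / "catalog.tsv", sep="\t")
    events_df = pd.read_csv(outdir / "events.tsv", sep="\t")
    classes_df = pd.read_csv(outdir / "classes.tsv", sep="\t", index_col="isoform_id")
    response_df = pd.read_csv(outdir / "response.tsv", sep="\t")

    # rebuild catalog chains from the written inputs + reads is indirect;
    # use the in-memory catalog when provided, else re-collapse the reads
    if catalog is None:
        reads = clp.read_bed12(outdir / "inputs" / "reads.bed")
        support = clp.read_junction_support(outdir / "inputs" / "junctions.tsv")
        candidates = clp.collapse_flnc(reads)
        catalog, _ = clp.label_novelty(
            clp.filter_catalog(candidates, support, sim.annotation), sim.annotation
        )
    matched = {
        rec.isoform_id: truth_by_chain.get(_chain_key(rec.transcript))
        for rec in catalog
    }
    n_catalog = len(catalog)
    n_truth = len(truth.structures)
    tp = sum(1 for v in matched.values() if v is not None)
    precision = tp / n_catalog if n_catalog else float("nan")
    recall = len({v for v in matched.values() if v is not None}) / n_truth

    # events: per matched isoform, the classified (type,index,delta) set
    ev_by_iso: dict[str, set] = {}
    for r in events_df.itertuples():
        if r.event_type != "complex":
            ev_by_iso.setdefault(r.isoform_id, set()).add(
                (r.event_type, int(r.index), int(r.delta_bp))
            )
    complex_by_iso = set(
        events_df[events_df["event_type"] == "complex"]["isoform_id"]
    )
    ev_ok = ev_total = 0
    cls_ok = cls_total = 0
    for rec in catalog:
        iso_truth = matched.get(rec.isoform_id)
        if iso_truth is None:
            continue
        planted = {
            (e.type, e.index, e.delta_bp) for e in truth.events[iso_truth]
        }
        ev_total += 1
        got = ev_by_iso.get(rec.isoform_id, set())
        if got == planted and rec.isoform_id not in complex_by_iso:
            ev_ok += 1
        if rec.isoform_id in classes_df.index:
            cls_total += 1
            if classes_df.at[rec.isoform_id, "class"] == truth.classes[iso_truth]:
                cls_ok += 1

    as_ok = as_total = de_ok = de_total = 0
    for r in response_df.itertuples():
        if r.sample_id.endswith("_0m"):
            continue
        as_total += 1
        de_total += 1
        if bool(r.as_diff) == truth.diff_spliced[r.gene_id][r.sample_id]:
            as_ok += 1
        if bool(r.tr_de) == truth.de[r.gene_id][r.sample_id]:
            de_ok += 1

    return {
        "catalog_precision": precision,
        "catalog_recall": recall,
        "event_recovery": ev_ok / ev_total if ev_total else float("nan"),
        "class_recovery": cls_ok / cls_total if cls_total else float("nan"),
        "splice_recovery": as_ok / as_total if as_total else float("nan"),
        "de_recovery": de_ok / de_total if de_total else float("nan"),
        "n_catalog": n_catalog,
        "n_truth_isoforms": n_truth,
    }


# ---------------------------------------------------------------------------
# family summary report (packaged fixture)


def family_summary_report(annotated_total: int = 36) -> dict:
    """Summary statistics over the packaged 18-gene wheat HSP90 table.

    Reports the total gene and isoform counts, per-subfamily mean isoform
    counts (1 decimal), the per-gene isoform-count range, per-subfamily
    exon-count uniformity, and the novel isoform count given how many
    isoforms were already annotated in the reference.
    """
    df = datasets.load_family_summary()
    if len(df) != 18:
        raise ValueError(f"family summary fixture must have 18 rows, got {len(df)}")
    per_subfamily = df.groupby("subfamily")["isoform_number"].mean().round(1)
    exon_uniform = df.groupby("subfamily")["exon_number"].nunique() == 1
    exon_count = df.groupby("subfamily")["exon_number"].first()
    total_isoforms = int(df["isoform_number"].sum())
    return {
        "n_genes": int(len(df)),
        "total_isoforms": total_isoforms,
        "mean_isoforms_per_subfamily": per_subfamily.to_dict(),
        "min_isoforms_per_gene": int(df["isoform_number"].min()),
        "max_isoforms_per_gene": int(df["isoform_number"].max()),
        "exon_count_uniform_per_subfamily": exon_uniform.to_dict(),
        "exon_count_per_subfamily": {k: int(v) for k, v in exon_count.items()},
        "annotated_isoforms": int(annotated_total),
        "novel_isoforms": total_isoforms - int(annotated_total),
        "n_triads_structure_conserved": int(
            sum(
                1
                for (_, sub) in df.groupby(["subfamily", "chromosome_group"])
                if sub["exon_number"].nunique() == 1 and len(sub) == 3
            )
        ),
    }
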