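# homeosplice

Isoform-resolution alternative-splicing (AS) analysis of homeologous gene
triads in polyploid transcriptomes.

Allopolyploid crops such as hexaploid wheat (*Triticum aestivum*, genomes
AABBDD) carry three near-identical copies — homeologs — of most genes, one
per subgenome. Homeolog triads are often indistinguishable at the level of
gene structure and transcriptional response, yet can diverge in *how* they
splice: which isoforms they produce, which of those isoforms dominate, and
when isoform usage shifts under stress. `homeosplice` implements the full
analysis chain needed to resolve that divergence from hybrid sequencing
data (full-length single-molecule reads plus short-read support), using the
wheat HSP90 heat-shock chaperone family as its worked case.

## What it computes

Given aligned full-length non-chimeric (FLNC) long reads, a reference
annotation, short-read junction support, and an isoform × sample count
matrix over a heat time course (organs G = filling grains, L = flag leaves;
time points 0m…4h):

1. **Isoform catalog** — FLNC reads mapping to the same locus with the same
   splice-junction chain are collapsed into one isoform; candidates are
   kept when read support ≥ 2, mean alignment identity ≥ 0.90 and every
   junction is short-read supported or annotated; isoforms are *annotated*
   or *novel* by junction-chain identity against the reference.
2. **Splicing modes and domain consequences** — each isoform is compared
   against its gene's canonical isoform (longest complete coding region)
   and classified into intron retention (IR), exon skipping (ES) and
   alternative 5'/3' splice sites (Alt5'SS/Alt3'SS); its predicted ORF
   determines which protein domains the isoform still encodes in frame.
3. **Isoform usage** — FPKM_i,s = counts · 10⁹ / (length · library size);
   the isoform expression percentage IEP_i,s = 100 · FPKM_i,s / Σ_{j∈gene}
   FPKM_j,s. Mean IEP > 30% in an organ ⇒ *major* isoform; IEP < 5% at all
   time points ⇒ *rare*; otherwise *minor*.
4. **Heat-response calls** — transcriptional response (TR): fold change ≥ 2
   with Benjamini–Hochberg FDR < 0.01 versus the same-organ 0m control,
   using an exact conditional negative-binomial test on the count pair;
   AS response: the expressed isoform set (FPKM ≥ 1, all junctions
   supported) differs between control and stress, or some isoform's IEP
   shifts by more than 30 percentage points.
5. **Triad reports** — per homeolog triad: exon-structure concordance,
   major-isoform counts, splicing-mode sets of the novel major isoforms
   (NIMIs), and concordance of AS-response timing.

A fully seeded synthetic generator (`homeosplice.simulate`) produces
genomes, triad annotations, planted isoforms and events, FLNC reads,
junction support and negative-binomial time-course counts with a complete
truth table, so every stage can be validated against known ground truth.

## Worked example

```sh
python examples/02_classify_splicing_modes.py
```

```
TaHSP90AA-2A: Alt5@intron/exon 1 (6 bp), Alt3@intron/exon 1 (6 bp); retained domains: ['HSP90']
TaHSP90AA-2B: IR@intron/exon 1 (112 bp); retained domains: ['HSP90']
TaHSP90AA-2D: ES@intron/exon 2 (36 bp); retained domains: ['HSP90']
```

The three AA-subfamily homeologs have identical 3-exon structures, yet
their novel major isoforms use three different splicing modes — alternative
donor *and* acceptor on intron 1 (A copy), intron-1 retention (B copy),
exon-2 skipping (D copy) — and each encodes a truncated peptide that keeps
only the C-terminal client-binding HSP90 domain, having lost the ATPase
(HATPase_c) domain. That is the family's signature pattern: conservation of
gene structure, divergence of splicing.

The family-level summary over the packaged 18-gene table:

```sh
python examples/06_family_summary.py
```

reports 18 genes and 126 isoforms (90 of them novel given 36 annotated),
per-subfamily mean isoform counts of 9.0 (B), 8.5 (AB), 7.0 (C2), 6.3 (AA)
and 2.7 (C1), a per-gene range of 2–13 isoforms, and uniform exon counts
within every subfamily (3, 3, 15, 19, 20) — structure conserved across all
six triads.

The other examples build a catalog from simulated reads, classify
abundance, call TR/AS responses, and print triad divergence reports. The
same pipeline runs from the shell:

```sh
homeosplice run --seed 42 --outdir my_run          # simulated inputs
homeosplice simulate --outdir my_sim               # write a data set
homeosplice family-report                          # 18-gene table summary
```

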