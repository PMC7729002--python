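# Methods

This note documents the models, rules and numerical choices behind
`homeosplice`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
reading existed.

## Coordinates and data model

All internal coordinates are 0-based half-open genomic intervals; GTF and
GFF3 files (1-based inclusive) are converted at the I/O boundary, which is
a bijection `[s, e] ↔ [s−1, e)`. Strand is stored on genes and
transcripts, but exon and intron intervals are always kept in genome
orientation; transcription-direction logic (event indices, donor/acceptor
sides, ORFs) is confined to the events module. A transcript's identity as
a splice form is its **junction chain** — the ordered introns derived as
gaps between consecutive exons; terminal-exon extents never enter
identity comparisons, because long-read 5'/3' ends are degradation- and
priming-sensitive while junctions are not. Zero-length exon gaps are
rejected at construction: adjacent exons must be merged upstream.

Both GTF and GFF3 dialects are auto-detected from the attribute-column
syntax; only `gene`, `transcript`/`mRNA` and `exon` features are
consumed. Gene lines may carry `subgenome`, `subfamily` and `triad_id`
attributes, which is how homeolog-triad membership enters the pipeline —
orthology inference is out of scope, the triad map is an input.

## Family membership filter

A candidate protein belongs to the HSP90 family when it carries **both**
the HATPase_c (ATP-binding) and HSP90 (client-binding/dimerization)
domains. Domain-hit tables (merged blast/hmmer evidence) are pre-filtered
at ingestion — e-value ≤ 1e-5, and identity > 50% for blast hits — then
de-duplicated per (protein, domain) pair, making the filter monotone in
evidence. Running the sequence searches themselves is out of scope; the
filter consumes precomputed hit tables.

## Isoform catalog

FLNC reads on the same chromosome and strand with identical junction
chains are collapsed into one candidate: internal exon boundaries come
from the shared junctions, terminal boundaries are the longest observed
extents, support is the member count, identity the member mean.
Mono-exonic reads have no junctions, so they are grouped by single-linkage
clustering: two reads link when they overlap and both ends agree within a
tolerance (default 100 bp).

Filtering keeps a candidate when support ≥ `min_support` (default 2
reads), mean identity ≥ `min_identity` (default 0.90), and **every**
junction is either short-read supported or present in an annotated
transcript. The per-junction, all-must-pass reading of "junction
verification" is an interpretation (a per-isoform reading is also
defensible); it is the stricter of the two and is applied uniformly.
Mono-exonic candidates pass on support + identity alone. The support and
identity defaults are conventional long-read practice and are
configurable.

Gene assignment uses maximal exonic overlap on the same strand (ties: the
larger overlap fraction of the isoform, then the smaller gene id);
antisense overlap never assigns. An isoform is *annotated* iff its chain
equals that of an annotated transcript of its gene (mono-exonic: span
agreement within the end tolerance), else *novel*.

## Event classification

Each isoform is compared to its gene's **canonical isoform** — the
annotated transcript with the longest complete coding region (ties:
longest spliced length, then smallest id). Chain differences are
classified genomically:

* canonical intron wholly inside an isoform exon → **IR** (delta = intron
  length);
* canonical internal exon with no isoform-exon overlap whose two flanking
  introns appear fused as one isoform intron → **ES** (delta = exon
  length);
* isoform intron overlapping exactly one canonical intron with one or two
  shifted boundaries → **Alt5'SS** for the donor-side shift and
  **Alt3'SS** for the acceptor-side shift (a both-ends shift yields both
  events). On the plus strand the donor is the genomic start boundary, on
  the minus strand the genomic end boundary.

Event indices are 1-based in transcription order and events are reported
5'→3'. Differences that match none of the four modes are reported as type
`complex` and excluded from four-class counts. Note the symmetry
semantics: flipping the strand of a fixed genomic structure swaps
Alt5↔Alt3 (donor and acceptor exchange sides), whereas mirroring all
coordinates *and* flipping the strand describes the identical gene and
leaves every classification unchanged. Both properties are enforced in
the test suite.

## ORFs and domain retention

ORFs are ATG-initiated, stop-terminated, scanned in the three forward
frames of the mature mRNA; the longest wins, ties to the 5'-most start,
and ORFs shorter than `min_orf_codons` (default 30 codons, excluding the
stop) are discarded as spurious micro-ORFs. Protein domains are annotated
as codon intervals on the canonical coding region and projected to
genomic codons through the canonical exon chain (partial-codon boundaries
are codon-aligned outward at ingestion). An isoform **retains** a domain
iff every genomic codon of the domain (i) survives in the isoform's
exons, (ii) maps to three consecutive isoform positions, and (iii) is
translated by the isoform's own longest ORF at a codon-consistent offset.
A frameshifting event upstream of a domain therefore abolishes it unless
a downstream start codon restores the frame — which is why retained sets
are not monotone under splicing and only `retained ⊆ annotated` is
guaranteed. Nonsense-mediated-decay prediction is deliberately out of
scope.

## Quantification and abundance classes

FPKM is counts × 10⁹ / (spliced length × library size), with library
size = total mapped fragments (no trimmed-mean normalization — the
published pipeline names FPKM only). The isoform expression percentage
IEP is the isoform's percent share of its gene's FPKM in a sample,
**undefined** (not zero) where the gene is unexpressed; undefined values
are excluded from means so that organ-absence does not masquerade as low
usage.

Classes use strict inequalities per the published wording: *major* iff
mean defined-IEP > 30 in at least one organ; *rare* iff IEP < 5 at every
sample where defined; *minor* otherwise; isoforms with no defined IEP
anywhere are reported separately as *unexpressed*. The catalog-wide
single class per isoform is the default (it reproduces a single
major/minor/rare partition of the catalog); a per-organ mode is available
behind a switch (`per_organ=True`) since the published text supports
either reading. Classes are scale-invariant: multiplying a sample's
counts by a constant changes nothing.

The most-abundant isoform per gene and sample is the FPKM argmax, ties
broken to the lexicographically smaller id and flagged, with a missing
marker when the gene is silent in that sample.

## Response calling

**Transcriptional (TR).** The published analysis used edgeR with fold
change ≥ 2 and FDR-adjusted p < 0.01 against the unstressed control; the
time course has no printed replicate structure, so the test is
re-specified as a replicate-free **exact conditional negative-binomial
test**: given the count pair (x_ctrl, x_trt) with sum s and library sizes
(N1, N2), the null splits s with means proportional to library size at a
fixed dispersion α (variance μ + αμ², default α = 0.1, configurable); the
two-sided p-value sums the probabilities of all splits at most as likely
as the observed one. In the α → 0 limit this reduces to the exact
conditional binomial test, and it approximates edgeR's exactTest
behaviour for single libraries. Benjamini–Hochberg adjustment runs across
genes within each contrast (per organ, per time point — contrasts are not
pooled across organs). The DE gate uses the count-level fold-change
estimate with half-count offsets; the display-oriented
`log2((FPKM+1)/(FPKM_ctrl+1))` fold change is computed separately with
pseudo-count 1.

**Differential splicing (AS).** A gene is differentially spliced between
control and a stress sample when (i) its expressed isoform set — FPKM ≥ 1
and all junctions short-read supported — differs (symmetric difference:
gain or loss both count), or (ii) some isoform's IEP changes by more than
30 **percentage points**. The absolute-points reading (not relative
change) was chosen because IEP is already a percentage and a relative
reading would trigger on rare isoforms' noise. Both criteria are
symmetric under control/treatment swap. Genes unexpressed in both samples
are not called and carry an `unexpressed` note; the machine-readable
reason set contains only `set_change`/`iep_shift` so that a non-empty
reason set is exactly equivalent to a positive call. TR and AS calls are
computed independently and never coupled.

## Triad reports

Per complete triad (one homeolog per subgenome): structure concordance
(identical canonical exon counts), per-homeolog major-isoform counts, the
event-type sets of the novel major isoforms (NIMIs), an AS-response
profile (the set of samples called differentially spliced) and per-sample
agreement of the top isoform's (novelty, event-set) signature. The triad
is **mode-divergent** iff major counts differ or the NIMI event-type sets
are not all equal — any inequality counts, since no magnitude threshold
for "different" is established; a mean pairwise Jaccard divergence of the
mode sets is additionally emitted as a purely descriptive score of this
package's own devising. AS-response concordance requires identical
sample sets *including timing*. Incomplete triads are reported with
not-evaluable fields rather than dropped.

## Synthetic-data generator

The generator emulates the study conditions end to end with full
determinism: one seed feeds stage-keyed streams (structure / reads /
counts), so outputs are byte-identical under a fixed seed and adding a
stage never perturbs earlier ones.

**Genes.** Each triad has one homeolog per subgenome (A, B, D; B copies
are placed on the minus strand to exercise strand logic) with identical
exon counts per subfamily — defaults 3, 3, 15, 19, 20 for subfamilies AA,
AB, B, C1, C2, one triad per subfamily, five triads by default. Coding
regions are built from a restricted alphabet so that exactly two start
codons exist (the true start and an in-frame restart at the head of the
last exon) and a single in-frame stop; every intron opens with an
in-frame stop so intron retention truncates read-through translation.
Two domains are planted per gene: a 5'-biased domain spanning exons 1–2
and a 3'-biased domain inside the last exon behind the restart codon.
The packaged AA demo triad is built by the same designer; its sequences
are synthetic — only splice structures and domain layout reproduce the
reported biology.

**Isoforms.** Per gene: the canonical (annotated) form plus three novel
forms — the novel major isoform with the subgenome-specific mode
(Alt5+Alt3 6 bp on intron 1 for A, intron-1 retention for B, exon-2
skipping for D), a minor isoform (9-bp donor shift at the last intron)
and a rare isoform (last-intron retention). By construction every novel
major isoform disrupts the 5' domain and keeps the 3' domain in frame.

**Reads.** Poisson(depth) FLNC reads per isoform (default mean 30),
emitted as aligned exon-chain records, not sequences — aligning raw long
reads is out of scope. Terminal ends are jittered inward up to 50 bp
(junctions never move at identity 1.0); below identity 1.0 a matching
fraction of reads receives one perturbed junction boundary.

**Counts.** Sample design is organs G and L × time points 0m, 5m, 10m,
30m, 1h, 4h, one library each (matching the apparent published design;
replicates are supported but default to 1, which is why the DE test is
replicate-free). Counts are negative-binomial with gene mean =
2000 × planted fold change and variance μ + αμ² (α default 0.1; α ≤ 1e-8
switches to deterministic rounded means, implementing the degenerate
noise-free mode exactly). The gene mean is split among isoforms
proportionally to planted usage × spliced length, so planted usage is
recovered exactly on the FPKM scale. Library sizes are emitted explicitly
(constant 10⁶ fragments per sample): the simulated panel represents a
small slice of a whole transcriptome, so total sequencing depth does not
track the panel's own induction — using panel column sums as library
sizes would let a coordinated 4-fold induction of most panel genes cancel
itself out of the normalization.

**Planted effects and truth.** Fold change 4 is planted for subgenomes A
and D at G_10m, G_30m and L_10m. Usage shifts swap the two major isoforms
from 52/35/12/1 to 12/75/12/1 percent — a 40-point swing, comfortably
beyond the 30-point call threshold — at G_30m for all homeologs of
even-numbered triads (concordant AS response) and at G_30m (A) / L_1h (B)
/ never (D) for odd-numbered triads (discordant timing). The truth table
records planted structures, novelty, events, classes, usage, fold
changes, DE flags and differential-splicing flags; planted classes are
derived by applying the 30/5 rule to the noise-free planted usage.

**What the generator does not emulate** — and hence what passing recovery
tests do not demonstrate about real data: sequence-level read errors and
chimeras, reference bias and alignment artefacts, fragment-level GC/length
bias, positional degradation beyond uniform end jitter, partially
expressed or silent homeologs, unannotated genes, and biological replicate
variability.

## Validation studies and problem sizes

The standard recovery study runs the full pipeline on five triads (60
planted isoforms, 1 770 reads, 12 samples) at depth 30, identity 1.0 and
dispersion α = 0.01 with the DE test's dispersion matched — count
dispersion low enough that usage noise stays well clear of the 30-point
call boundary and the 30/5 class boundaries (at α = 0.01 and the planted
margins, realized IEP standard deviations are a few points at most).
Under these conditions catalog precision and recall, event recovery,
class recovery, differential-splicing-flag recovery and DE-flag recovery
are all exactly 1.0, across seeds. At the generator's default α = 0.1,
usage noise of the major isoforms (several points of IEP per sample)
can cross the 30-point shift boundary, so exact flag recovery is only
claimed for low-dispersion conditions.

The DE caller's null behaviour is measured on 1000 genes × 500 runs of
NB(μ = 100, α = 0.1) with no planted effect: the mean fraction of genes
passing BH-adjusted p < 0.01 is far below the nominal level (the exact
conditional test is conservative at moderate means). Power is measured
at planted fold changes 1, 2 and 4 (200 genes × 10 runs each) and is
monotone non-decreasing; absolute power at fold change 2 is small for a
replicate-free pair of libraries at α = 0.1, which is the honest cost of
the design, not a defect of the test.

These sizes keep the whole suite and the acceptance script to a couple of
minutes on a single CPU.

## Known limitations

* Isoform abundance is consumed as a given count matrix; EM-style
  transcript quantification from reads (salmon/kallisto) is out of scope.
* The DE test's fixed dispersion is an assumption, not an estimate; with
  replicates one would estimate it empirically (edgeR/DESeq2) instead.
* Junction verification is per-junction and binary; no junction-quality
  scores are modelled.
* Complex splicing differences are flagged but not decomposed.
* The triad map must be supplied (or simulated); the package does not
  infer homeology.
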