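"""Classify splicing modes and domain consequences in the AA demo triad.

Loads the packaged reconstruction of the three AA-subfamily wheat HSP90
homeologs and compares each novel major isoform against the canonical
(longest-ORF) isoform: the A copy uses alternative 5' and 3' splice sites
on intron 1, the B copy retains intron 1, the D copy skips exon 2 — three
different modes on identical gene structures. Each novel isoform's
predicted ORF keeps only the C-terminal HSP90 (client-binding) domain,
i.e. it encodes a truncated peptide without the ATPase domain.
"""
from homeosplice.datasets import load_aa_triad
from homeosplice.events import canonical_isoform, classify_events, domain_retention

genes, genome, domains = load_aa_triad()
for gene in genes:
    canonical = canonical_isoform(gene, genome)
    nimi = gene.transcript(f"{gene.gene_id}.nimi")
    events = classify_events(nimi, canonical)
    retained = domain_retention(nimi, canonical, domains[gene.gene_id], genome)
    modes = ", ".join(f"{e.type}@intron/exon {e.index} ({e.delta_bp} bp)" for e in events)
    print(f"{gene.gene_id}: {modes}; retained domains: {sorted(retained)}")
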