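"""Reproduce the family-level summary from the packaged gene table.

The packaged table lists the 18 hexaploid-wheat HSP90 genes with their
subfamily, subgenome, exon count and isoform count. The report recovers
the published family statistics: 126 isoforms (90 novel given 36
annotated), per-subfamily means, and exon-count uniformity within each
subfamily (3, 3, 15, 19, 20 exons for AA, AB, B, C1, C2).
"""
import json

from homeosplice.pipeline import family_summary_report

report = family_summary_report(annotated_total=36)
print(json.dumps(report, indent=1))
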