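"""Homeolog-triad conservation/divergence reporting.

A triad is the set of three homeologous gene copies, one per subgenome
(A, B, D), of an allopolyploid. The report summarizes, per triad: exon
structure concordance of the canonical transcripts; major-isoform counts
and the splicing-mode sets of the newly identified major isoforms (NIMIs);
concordance of the differential-splicing response profiles across the
heat time course; and per-sample agreement of the most abundant isoform's
signature.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

SUBGENOMES = ("A", "B", "D")


@dataclass
class TriadReport:
    triad_id: str
    subfamily: str | None
    complete: bool
    exon_counts: dict[str, int | None]
    structure_conserved: bool | None
    major_counts: dict[str, int | None]
    nimi_event_sets: dict[str, frozenset[str] | None]
    nimi_modes_divergent: bool | None
    nimi_mode_jaccard_divergence: float | None  # descriptive score, not a call
    as_response_profile: dict[str, frozenset[str] | None]
    as_response_concordant: bool | None
    top_isoform_agreement: dict[str, bool | None]

    def to_row(self) -> dict:
        fmt_set = lambda s: ";".join(sorted(s)) if s is not None else "NA"
        return {
            "triad_id": self.triad_id,
            "subfamily": self.subfamily or "NA",
            "complete": self.complete,
            **{f"exons_{s}": self.exon_counts.get(s) for s in SUBGENOMES},
            "structure_conserved": self.structure_conserved,
            **{f"major_{s}": self.major_counts.get(s) for s in SUBGENOMES},
            **{
                f"nimi_modes_{s}": fmt_set(self.nimi_event_sets.get(s))
                for s in SUBGENOMES
            },
            "nimi_modes_divergent": self.nimi_modes_divergent,
            "nimi_mode_jaccard_divergence": self.nimi_mode_jaccard_divergence,
            **{
                f"as_profile_{s}": fmt_set(self.as_response_profile.get(s))
                for s in SUBGENOMES
            },
            "as_response_concordant": self.as_response_concordant,
            "n_samples_top_isoform_agreement": (
                sum(1 for v in self.top_isoform_agreement.values() if v)
                if self.top_isoform_agreement
                else None
            ),
        }


def structure_concordance(
    exon_counts: Mapping[str, int | None]
) -> tuple[bool | None, dict[str, int | None]]:
    """True iff the three canonical transcripts have identical exon counts;
    None (incomplete) when any homeolog is missing."""
    counts = {s: exon_counts.get(s) for s in SUBGENOMES}
    if any(v is None for v in counts.values()):
        return None, counts
    vals = set(counts.values())
    return len(vals) == 1, counts


def _jaccard_divergence(sets: Sequence[frozenset[str]]) -> float:
    """Mean pairwise (1 - Jaccard) of the NIMI mode sets; a descriptive
    divergence score of the package's own devising, emitted alongside the
    boolean call."""
    pairs = [(0, 1), (0, 2), (1, 2)]
    vals = []
    for a, b in pairs:
        u = sets[a] | sets[b]
        vals.append(0.0 if not u else 1.0 - len(sets[a] & sets[b]) / len(u))
    return sum(vals) / len(vals)


def major_isoform_profile(
    gene_by_subgenome: Mapping[str, str | None],
    classes: pd.DataFrame,  # columns: isoform_id, gene_id, class, novelty
    events: pd.DataFrame,  # columns: isoform_id, event_type
) -> tuple[dict[str, int | None], dict[str, frozenset[str] | None], bool | None, float | None]:
    """Per-homeolog major-isoform counts and NIMI splicing-mode sets.

    A NIMI is a novel (unannotated) isoform classified major. The triad is
    mode-divergent iff major counts differ or the NIMI event-type sets are
    not all equal.
    """
    major_counts: dict[str, int | None] = {}
    nimi_sets: dict[str, frozenset[str] | None] = {}
    ev_by_iso = (
        events.groupby("isoform_id")["event_type"].apply(frozenset)
        if len(events)
        else pd.Series(dtype=object)
    )
    for s in SUBGENOMES:
        gid = gene_by_subgenome.get(s)
        if gid is None:
            major_counts[s] = None
            nimi_sets[s] = None
            continue
        sub = classes[classes["gene_id"] == gid]
        majors = sub[sub["class"] == "major"]
        major_counts[s] = int(len(majors))
        nimis = majors[majors["novelty"] == "novel"]["isoform_id"]
        modes: set[str] = set()
        for iso in nimis:
            modes |= set(ev_by_iso.get(iso, frozenset()))
        nimi_sets[s] = frozenset(modes)
    if any(v is None for v in major_counts.values()):
        return major_counts, nimi_sets, None, None
    sets = [nimi_sets[s] for s in SUBGENOMES]
    divergent = len(set(major_counts.values())) > 1 or len(set(sets)) > 1
    return major_counts, nimi_sets, divergent, _jaccard_divergence(sets)


def as_response_concordance(
    gene_by_subgenome: Mapping[str, str | None],
    response: pd.DataFrame,  # columns: gene_id, sample_id, as_diff
) -> tuple[dict[str, frozenset[str] | None], bool | None]:
    """Per-homeolog sets of samples with a differential-splicing call;
    concordant iff the three sets (including timing) are identical."""
    profiles: dict[str, frozenset[str] | None] = {}
    for s in SUBGENOMES:
        gid = gene_by_subgenome.get(s)
        if gid is None:
            profiles[s] = None
            continue
        sub = response[(response["gene_id"] == gid) & response["as_diff"]]
        profiles[s] = frozenset(sub["sample_id"])
    if any(v is None for v in profiles.values()):
        return profiles, None
    return profiles, len({profiles[s] for s in SUBGENOMES}) == 1


def _top_isoform_agreement(
    gene_by_subgenome: Mapping[str, str | None],
    top: pd.DataFrame,  # columns: gene_id, sample_id, isoform_id
    signatures: Mapping[str, tuple],  # isoform -> (novelty, event-type set)
) -> dict[str, bool | None]:
    out: dict[str, bool | None] = {}
    gids = [gene_by_subgenome.get(s) for s in SUBGENOMES]
    if any(g is None for g in gids):
        return {}
    for sample, sub in top.groupby("sample_id"):
        sigs = []
        for gid in gids:
            row = sub[sub["gene_id"] == gid]
            iso = row["isoform_id"].iloc[0] if len(row) else None
            if iso is None or pd.isna(iso):
                sigs.append(None)
            else:
                sigs.append(signatures.get(iso))
        out[sample] = (None not in sigs) and len(set(sigs)) == 1
    return out


def build_triad_report(
    triad_id: str,
    triad_map: pd.DataFrame,  # rows of this triad: gene_id, subgenome, subfamily
    exon_counts: Mapping[str, int],  # gene_id -> canonical exon count
    classes: pd.DataFrame,
    events: pd.DataFrame,
    response: pd.DataFrame | None,
    top: pd.DataFrame | None,
) -> TriadReport:
    gene_by_sub: dict[str, str | None] = {s: None for s in SUBGENOMES}
    subfamily = None
    for _, row in triad_map.iterrows():
        gene_by_sub[row["subgenome"]] = row["gene_id"]
        subfamily = row.get("subfamily", subfamily)
    complete = all(gene_by_sub[s] is not None for s in SUBGENOMES)

    ex = {
        s: (exon_counts.get(gene_by_sub[s]) if gene_by_sub[s] else None)
        for s in SUBGENOMES
    }
    conserved, ex = structure_concordance(ex)
    major_counts, nimi_sets, divergent, jaccard = major_isoform_profile(
        gene_by_sub, classes, events
    )
    if response is not None:
        profiles, concordant = as_response_concordance(gene_by_sub, response)
    else:
        profiles, concordant = {s: None for s in SUBGENOMES}, None

    agreement: dict[str, bool | None] = {}
    if top is not None and complete:
        sig = {}
        ev_by_iso = (
            events.groupby("isoform_id")["event_type"].apply(frozenset)
            if len(events)
            else pd.Series(dtype=object)
        )
        for _, row in classes.iterrows():
            sig[row["isoform_id"]] = (
                row["novelty"],
                ev_by_iso.get(row["isoform_id"], frozenset()),
            )
        agreement = _top_isoform_agreement(gene_by_sub, top, sig)

    return TriadReport(
        triad_id=triad_id,
        subfamily=subfamily,
        complete=complete,
        exon_counts=ex,
        structure_conserved=conserved,
        major_counts=major_counts,
        nimi_event_sets=nimi_sets,
        nimi_modes_divergent=divergent,
        nimi_mode_jaccard_divergence=jaccard,
        as_response_profile=profiles,
        as_response_concordant=concordant,
        top_isoform_agreement=agreement,
    )


def triad_summary(reports: Sequence[TriadReport]) -> pd.DataFrame:
    """One row per triad plus a totals row of headline counts."""
    cols = [
        "triad_id", "subfamily", "complete",
        "exons_A", "exons_B", "exons_D", "structure_conserved",
        "major_A", "major_B", "major_D",
        "nimi_modes_A", "nimi_modes_B", "nimi_modes_D",
        "nimi_modes_divergent", "nimi_mode_jaccard_divergence",
        "as_profile_A", "as_profile_B", "as_profile_D",
        "as_response_concordant", "n_samples_top_isoform_agreement",
    ]
    rows = [r.to_row() for r in reports]
    df = pd.DataFrame(rows, columns=cols)
    totals = {c: "" for c in cols}
    totals["triad_id"] = "TOTAL"
    totals["structure_conserved"] = sum(
        1 for r in reports if r.structure_conserved
    )
    totals["nimi_modes_divergent"] = sum(
        1 for r in reports if r.nimi_modes_divergent
    )
    totals["as_response_concordant"] = sum(
        1 for r in reports if r.as_response_concordant is False
    )
    df = pd.concat([df, pd.DataFrame([totals])], ignore_index=True)
    return df
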