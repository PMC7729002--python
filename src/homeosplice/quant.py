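"""Expression quantification and isoform abundance classes.

Abundance is expressed as FPKM (fragments per kilobase of exon model per
million mapped fragments). The isoform expression percentage (IEP) is one
isoform's share, in percent, of its gene's summed FPKM in a sample; it is
undefined (NaN) in samples where the gene is not expressed. Isoforms are
classified from their IEP profile across an organ time course:

* major  — mean defined-IEP strictly above ``iep_major`` (default 30) in
  at least one organ;
* rare   — IEP strictly below ``iep_rare`` (default 5) at every sample
  where it is defined;
* minor  — everything else;
* unexpressed — no defined IEP anywhere (reported separately).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SampleDesign:
    """Ordered organ x time-point sample layout with one control (time
    ``0m``) per organ; sample ids look like ``G_5m`` / ``L_0m``."""

    samples: tuple[tuple[str, str], ...]  # (organ, time) in column order

    def __post_init__(self) -> None:
        ids = [f"{o}_{t}" for o, t in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in design")
        for organ in self.organs:
            n_ctrl = sum(1 for o, t in self.samples if o == organ and t == "0m")
            if n_ctrl != 1:
                raise ValueError(f"organ {organ} needs exactly one 0m control")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{o}_{t}" for o, t in self.samples]

    @property
    def organs(self) -> list[str]:
        seen: list[str] = []
        for o, _ in self.samples:
            if o not in seen:
                seen.append(o)
        return seen

    def organ_of(self, sample_id: str) -> str:
        return sample_id.split("_", 1)[0]

    def control_of(self, sample_id: str) -> str:
        return f"{self.organ_of(sample_id)}_0m"

    def is_control(self, sample_id: str) -> bool:
        return sample_id.endswith("_0m")

    def samples_of(self, organ: str) -> list[str]:
        return [f"{o}_{t}" for o, t in self.samples if o == organ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "organ": [o for o, _ in self.samples],
                "time": [t for _, t in self.samples],
                "is_control": [t == "0m" for _, t in self.samples],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        return cls(tuple(zip(df["organ"], df["time"])))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def fpkm(
    counts: pd.DataFrame,
    lengths: Mapping[str, int] | pd.Series,
    library_sizes: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM matrix: counts * 1e9 / (length_bp * library_size).

    ``library_sizes`` defaults to the per-sample column sums of ``counts``
    (total mapped fragments).
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing lengths for isoforms: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("spliced lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    return counts.div(lengths, axis=0).div(library_sizes, axis=1) * 1e9


def iep(fpkm_matrix: pd.DataFrame, gene_map: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Isoform expression percentage per gene and sample.

    ``iep[i, s] = 100 * fpkm[i, s] / sum_{j in gene(i)} fpkm[j, s]``;
    NaN where the gene's summed FPKM in the sample is zero.
    """
    gene_map = pd.Series(gene_map).reindex(fpkm_matrix.index)
    if gene_map.isna().any():
        missing = gene_map.index[gene_map.isna()].tolist()
        raise ValueError(f"isoforms without gene assignment: {missing[:5]}")
    gene_totals = fpkm_matrix.groupby(gene_map).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * fpkm_matrix / gene_totals
    return out.where(gene_totals > 0)


def classify_abundance(
    iep_matrix: pd.DataFrame,
    design: SampleDesign,
    iep_major: float = 30.0,
    iep_rare: float = 5.0,
    per_organ: bool = False,
) -> pd.DataFrame:
    """Classify isoforms into major / minor / rare from their IEP profile.

    Undefined IEPs are excluded from organ means (not treated as zero).
    With ``per_organ=True`` a separate class per organ is returned in
    columns ``class_<organ>`` in addition to the catalog-wide ``class``.
    """
    organs = design.organs
    means = {}
    for organ in organs:
        cols = [c for c in design.samples_of(organ) if c in iep_matrix.columns]
        means[f"mean_iep_{organ}"] = iep_matrix[cols].mean(axis=1, skipna=True)
    out = pd.DataFrame(means, index=iep_matrix.index)

    defined = iep_matrix.notna()
    any_defined = defined.any(axis=1)
    all_below_rare = (iep_matrix < iep_rare) | ~defined

    def _one(mean_cols: Sequence[str], rare_mask: pd.Series) -> pd.Series:
        is_major = pd.concat(
            [out[c] > iep_major for c in mean_cols], axis=1
        ).any(axis=1)
        cls = pd.Series("minor", index=out.index, dtype=object)
        cls[rare_mask] = "rare"
        cls[is_major] = "major"  # major takes precedence over rare-by-mask
        cls[~any_defined] = "unexpressed"
        return cls

    out["class"] = _one(list(means), all_below_rare.all(axis=1) & any_defined)
    if per_organ:
        for organ in organs:
            cols = [c for c in design.samples_of(organ) if c in iep_matrix.columns]
            organ_defined = defined[cols].any(axis=1)
            organ_rare = (all_below_rare[cols]).all(axis=1) & organ_defined
            is_major = out[f"mean_iep_{organ}"] > iep_major
            cls = pd.Series("minor", index=out.index, dtype=object)
            cls[organ_rare] = "rare"
            cls[is_major] = "major"
            cls[~organ_defined] = "unexpressed"
            out[f"class_{organ}"] = cls
    return out


def most_abundant(
    fpkm_matrix: pd.DataFrame, gene_map: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per gene and sample, the isoform with the highest FPKM.

    Ties are broken toward the lexicographically smaller isoform id and
    flagged; genes with zero FPKM in a sample get a missing marker (NaN).
    Returned long-format columns: gene_id, sample_id, isoform_id, fpkm,
    tie.
    """
    gene_map = pd.Series(gene_map).reindex(fpkm_matrix.index)
    rows = []
    for gid, sub in fpkm_matrix.groupby(gene_map):
        sub = sub.sort_index()  # lexicographic tie-break via first idxmax
        for sample in fpkm_matrix.columns:
            col = sub[sample]
            total = col.sum()
            if total <= 0:
                rows.append((gid, sample, np.nan, 0.0, False))
                continue
            top = col.idxmax()
            tie = (col == col.max()).sum() > 1
            rows.append((gid, sample, top, float(col.max()), bool(tie)))
    return pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "isoform_id", "fpkm", "tie"]
    )
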