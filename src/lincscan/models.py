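"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; GTF and
VCF I/O converts from/to the 1-based inclusive conventions of those formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

Interval = tuple[int, int]


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass
class TranscriptModel:
    """One assembled transcript with the attributes the filter cascade needs.

    exons are sorted, pairwise non-overlapping 0-based half-open intervals.
    cpc_score is the coding-potential score (negative = non-coding);
    homology_hits are (alignment_length_bp, e_value) pairs from a protein
    database search. Either may be None when the corresponding filter is
    disabled.
    """

    id: str
    chrom: str
    strand: str
    exons: list[Interval]
    fpkm: float = 0.0
    coverage: float = 0.0
    cpc_score: float | None = None
    homology_hits: list[tuple[float, float]] = field(default_factory=list)
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"transcript {self.id}: empty exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"transcript {self.id}: exons unsorted or overlapping at {s}"
                )
            prev_end = e
        if self.fpkm < 0 or self.coverage < 0:
            raise ValidationError(f"transcript {self.id}: negative fpkm/coverage")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class GeneLocus:
    """A gene-level interval grouping one or more transcripts."""

    id: str
    chrom: str
    start: int
    end: int
    biotype: str  # lincRNA_candidate | protein_coding | known_lncRNA
    transcript_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"locus {self.id}: empty span")

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM matrix with a sample -> tissue-group map."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    groups: pd.Series  # index: sample ids, values: group labels

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.groups.index]
        if missing:
            raise ValidationError(f"samples without group label: {missing[:5]}")
        self.groups = self.groups.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def group_names(self) -> list[str]:
        return list(pd.unique(self.groups))

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.groups.index[self.groups == group]
        return list(sel)

    def group_summary(self, how: str = "max", groups: Sequence[str] | None = None,
                      transform=None) -> pd.DataFrame:
        """Per-gene per-group summary (max or mean) of (optionally transformed)
        FPKM. Returns genes x groups."""
        use = groups if groups is not None else self.group_names
        vals = self.values
        if transform is not None:
            vals = transform(vals)
        cols = {}
        for g in use:
            smp = self.samples_in_group(g)
            if not smp:
                raise ValidationError(f"group {g!r} has zero samples")
            block = vals[smp]
            cols[g] = block.max(axis=1) if how == "max" else block.mean(axis=1)
        return pd.DataFrame(cols)

    def to_tsv(self, path, sample_map_path=None) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        if sample_map_path is not None:
            self.groups.rename("group").to_csv(
                sample_map_path, sep="\t", index_label="sample_id"
            )

    @classmethod
    def from_tsv(cls, path, sample_map_path) -> "ExpressionMatrix":
        vals = pd.read_csv(path, sep="\t", index_col="gene_id")
        groups = pd.read_csv(sample_map_path, sep="\t", index_col="sample_id")["group"]
        return cls(vals, groups)


@dataclass
class SnpGenotypePanel:
    """Biallelic SNPs with per-population allele counts.

    snps is a DataFrame with columns: chrom, pos (1-based), n_ref, c_ref,
    n_dom, c_dom — n_* the number of sampled alleles per population, c_* the
    count of the (arbitrary but consistent) A allele. Positions are strictly
    increasing within each chromosome.
    """

    snps: pd.DataFrame

    REQUIRED = ("chrom", "pos", "n_ref", "c_ref", "n_dom", "c_dom")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.snps.columns:
                raise ValidationError(f"panel missing column {col!r}")
        self.snps = self.snps.reset_index(drop=True)
        df = self.snps
        if ((df["c_ref"] > df["n_ref"]) | (df["c_dom"] > df["n_dom"])).any():
            raise ValidationError("allele count exceeds sampled alleles")
        if ((df["c_ref"] < 0) | (df["c_dom"] < 0)).any():
            raise ValidationError("negative allele count")
        for chrom, grp in df.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on {chrom}"
                )

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def p_ref(self) -> np.ndarray:
        return self.snps["c_ref"].to_numpy(float) / self.snps["n_ref"].to_numpy(float)

    @property
    def p_dom(self) -> np.ndarray:
        return self.snps["c_dom"].to_numpy(float) / self.snps["n_dom"].to_numpy(float)

    def to_tsv(self, path) -> None:
        self.snps.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SnpGenotypePanel":
        return cls(pd.read_csv(path, sep="\t"))


def loci_to_dataframe(loci: Iterable[GeneLocus]) -> pd.DataFrame:
    rows = [
        {"id": l.id, "chrom": l.chrom, "start": l.start, "end": l.end,
         "biotype": l.biotype}
        for l in loci
    ]
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "biotype"])
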