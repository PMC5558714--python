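"""Intersection of GWAS significant SNPs with lincRNA loci.

A SNP at 1-based position P is inside a 0-based half-open locus [start,
end) iff start < P <= end. Duplicate (chrom, pos) rows — the same SNP
reported for several traits — count once for locus membership.
"""

from __future__ import annotations

import pandas as pd

from .models import GeneLocus, ValidationError

GWAS_COLUMNS = ("snp_id", "chrom", "pos", "trait")


def read_gwas_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in GWAS_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"GWAS table missing column {col!r}")
    if (df["pos"] <= 0).any():
        raise ValidationError("GWAS positions must be positive (1-based)")
    return df


def snps_in_loci(table: pd.DataFrame, loci: list[GeneLocus]) -> dict:
    """Count GWAS SNPs inside loci.

    Returns {"n_snps_in": distinct (chrom,pos) inside any locus,
    "n_loci_hit": distinct loci containing >=1 SNP, "assignments":
    DataFrame(snp_id, chrom, pos, trait, locus_id)}. A SNP inside two
    overlapping loci is assigned to both.
    """
    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)

    rows = []
    for snp in table.itertuples(index=False):
        pos = int(snp.pos)
        for locus in by_chrom.get(str(snp.chrom), ()):
            if locus.start < pos <= locus.end:
                rows.append({"snp_id": snp.snp_id, "chrom": snp.chrom,
                             "pos": pos, "trait": snp.trait,
                             "locus_id": locus.id})
    assignments = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "trait", "locus_id"]
    )
    n_snps_in = len(assignments[["chrom", "pos"]].drop_duplicates())
    n_loci_hit = assignments["locus_id"].nunique()
    return {"n_snps_in": int(n_snps_in), "n_loci_hit": int(n_loci_hit),
            "assignments": assignments}


def array_fraction(n_significant: int, n_array: int) -> dict[str, float]:
    """Percentage of an array's SNPs that are GWAS-significant.

    Returns both the unrounded percentage and the value rounded to two
    decimals (the form usually reported)."""
    if n_array <= 0:
        raise ValidationError("array size must be positive")
    if not 0 <= n_significant <= n_array:
        raise ValidationError("significant SNP count outside [0, array size]")
    pct = 100.0 * n_significant / n_array
    return {"percent": pct, "percent_rounded": round(pct, 2)}
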