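"""VCF v4.2 I/O for the two-population SNP panel.

Writing emits diploid GT fields whose allele counts reproduce the panel
exactly (alternate alleles are assigned to the leading haplotypes of each
population; counts, not haplotype identities, are the object of interest).
Reading goes through cyvcf2 and reconstructs per-population allele counts
from the sample genotypes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import SnpGenotypePanel, ValidationError


def write_vcf(panel: SnpGenotypePanel, path, ref_prefix: str = "ref",
              dom_prefix: str = "dom") -> None:
    df = panel.snps
    n_ref = int(df["n_ref"].iloc[0])
    n_dom = int(df["n_dom"].iloc[0])
    if (df["n_ref"] != n_ref).any() or (df["n_dom"] != n_dom).any():
        raise ValidationError("VCF export needs constant sample sizes")
    if n_ref % 2 or n_dom % 2:
        raise ValidationError("haplotype counts must be even for diploid VCF")
    ref_samples = [f"{ref_prefix}_{i + 1}" for i in range(n_ref // 2)]
    dom_samples = [f"{dom_prefix}_{i + 1}" for i in range(n_dom // 2)]

    def gts(count: int, n_hap: int) -> list[str]:
        # alt allele on the first `count` haplotypes
        out = []
        for i in range(0, n_hap, 2):
            a = 1 if i < count else 0
            b = 1 if i + 1 < count else 0
            out.append(f"{a}/{b}")
        return out

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(df["chrom"]):
            last = df.loc[df["chrom"] == chrom, "pos"].max()
            fh.write(f"##contig=<ID={chrom},length={int(last) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ref_samples + dom_samples) + "\n")
        for i, row in enumerate(df.itertuples(index=False)):
            fields = [str(row.chrom), str(int(row.pos)), f"snp_{i + 1}",
                      "A", "G", ".", "PASS", ".", "GT"]
            fields += gts(int(row.c_ref), n_ref)
            fields += gts(int(row.c_dom), n_dom)
            fh.write("\t".join(fields) + "\n")


def read_panel_vcf(path, ref_samples: list[str] | None = None,
                   dom_samples: list[str] | None = None,
                   ref_prefix: str = "ref", dom_prefix: str = "dom"
                   ) -> SnpGenotypePanel:
    """Build an allele-count panel from a VCF; populations given either as
    explicit sample lists or by sample-name prefix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if ref_samples is None:
        ref_samples = [s for s in samples if s.startswith(ref_prefix + "_")]
    if dom_samples is None:
        dom_samples = [s for s in samples if s.startswith(dom_prefix + "_")]
    if not ref_samples or not dom_samples:
        raise ValidationError("both populations need >=1 sample in the VCF")
    ref_idx = np.array([samples.index(s) for s in ref_samples])
    dom_idx = np.array([samples.index(s) for s in dom_samples])

    rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic only
        g = np.array(var.genotypes, dtype=object)
        alleles = np.array([[int(a[0]), int(a[1])] for a in g])
        rows.append({
            "chrom": var.CHROM, "pos": var.POS,
            "n_ref": 2 * len(ref_idx),
            "c_ref": int(alleles[ref_idx].sum()),
            "n_dom": 2 * len(dom_idx),
            "c_dom": int(alleles[dom_idx].sum()),
        })
    return SnpGenotypePanel(pd.DataFrame(
        rows, columns=["chrom", "pos", "n_ref", "c_ref", "n_dom", "c_dom"]))
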