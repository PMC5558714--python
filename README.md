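# lincscan

Pipeline for annotating long intergenic non-coding RNAs (lincRNAs) and
screening them for signatures of artificial selection under domestication,
with a fully seeded synthetic-data generator for testing every stage
against known ground truth.

## The problem

Domestication reshapes behavior, morphology and physiology, and most
population-genomic studies of that process have looked only at
protein-coding genes. LincRNAs — transcripts ≥ 200 nt from intergenic
regions with no protein-coding potential — are a plausible but
under-examined substrate of selection. Given assembled transcripts, an
expression matrix across tissues, and SNP allele frequencies from a wild
(reference) and a domestic population, this package:

1. **Filters candidate lincRNAs** by the cascade: exon number > 1,
   FPKM > 1, assembler coverage > 3, length ≥ 200 nt, coding-potential
   score < 0, and no significant protein homology hit (alignment > 30 bp
   and e < 10⁻³); loci with any significantly-hit transcript are abandoned
   whole.
2. **Classifies novelty** against a known-lncRNA reference using
   structural class codes (`=`, `c`, `j`, `o`, `p`, `u`); loci whose
   transcripts all score `u` are novel.
3. **Assigns each lincRNA its closest protein-coding gene** (signed
   distance on the forward genome axis) and compares Pearson correlations
   of FPKM between lincRNA–neighbor, adjacent coding–coding, and random
   coding pairs (matched counts; t and Wilcoxon rank-sum tests).
4. **Scores tissue specificity** two ways:
   the tissue specificity index
   τ = Σᵢ(1 − xᵢ)/(N − 1) with xᵢ max-normalized per-tissue expression
   (specific at τ ≥ 0.95), and the min-ratio score
   1 − minᵢ(M(i)/E(i)) on per-group maxima of log₂(FPKM+1)
   (specific at ≥ 0.75).
5. **Calls differential expression** between two conditions: Student's
   t-test on log₂(FPKM+1), Benjamini–Hochberg adjustment, called when
   adjusted p < 0.05, fold change > 2 or < 0.5, and mean FPKM > 1 in at
   least one condition.
6. **Runs a three-statistic selection scan**: per-SNP Weir–Cockerham
   F_ST (Hudson's estimator optional); sliding-window mean F_ST (50 kb);
   nucleotide diversity π = Σ 2p(1−p)·n/(n−1) per window length, with
   Δπ = π_wild − π_domestic (50-kb windows, 25-kb step); pooled
   heterozygosity Hp = 2·ΣnMAJ·ΣnMIN/(ΣnMAJ + ΣnMIN)² in 40-kb windows.
   The top 5% most extreme windows per statistic (F_ST, Δπ high; Hp low)
   are candidate sweep regions; lincRNA loci overlapping them are
   candidates, combined by exact union/intersection bookkeeping.
7. **Intersects GWAS significant SNPs** with lincRNA loci and reports the
   fraction of the genotyping array they represent.

## Worked example

```bash
cat > run.yaml <<EOF
seed: 1
outdir: run_out
EOF
lincscan run --config run.yaml
```

On the default synthetic genome (2 chromosomes × 5.025 Mb, 200 coding and
100 lincRNA loci, 5 tissue groups × 10 samples, ~10,050 SNPs, 20 planted
sweeps) this prints a stage report containing:

```
"filter":  {"status": "complete", "n_retained": 93, "n_rejected": 38,
            "n_loci": 78, "n_novel": 38, "n_known": 40,
            "median_length": 938.0, "mean_exon_count": 3.0}
"specificity": {"status": "complete", "n_tsi": 20, "n_minratio": 20,
            "minratio_in_tsi_fraction": 1.0}
"de":      {"status": "complete", "n_de": 10, "sensitivity": 1.0,
            "false_discovery_fraction": 0.0}
"scan":    {"status": "complete", "n_fst": 6, "n_delta_pi": 4, "n_hp": 6,
            ..., "all_three": 3, "union": 7}
"gwas":    {"status": "complete", "n_snps_in": 8, "n_loci_hit": 7}
```

Reading: 93 of 131 simulated lincRNA transcripts survive the filter
cascade (the generator plants single-exon and weakly expressed decoys),
leaving 78 loci of which 38 match no known-lncRNA reference and are novel.
All 20 planted tissue-specific genes are recovered by both specificity
scores, all 10 planted DE genes are called with no false calls, and the
selection scan flags 7 lincRNA loci that overlap planted sweep windows
(3 by all three statistics). 8 of the 10 planted in-locus GWAS SNPs fall
in loci that survived filtering. Every output is also written as
TSV/GTF/JSON under `run_out/`.

The same stages are available individually (`lincscan simulate`,
`filter-lincrnas`, `neighbors`, `specificity`, `de`, `scan`,
`gwas-overlap`) and as library functions.

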