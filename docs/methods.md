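# Methods

## Scope and conventions

All genomic coordinates are 0-based half-open internally; GTF and VCF I/O
convert to and from the 1-based inclusive conventions of those formats. A
GWAS SNP at 1-based position P lies in a locus [start, end) iff
start < P ≤ end. Expression is in FPKM; log transforms are log₂(FPKM+1)
wherever a log scale is used (differential expression, the min-ratio
specificity path). "Coverage" is the assembler-reported per-transcript
attribute consumed from the GTF; it is never recomputed from reads. All
structural comparisons are strand-agnostic, matching pipelines that
process mixed-strandedness libraries as unstranded.

## Filter cascade and class codes

A transcript is retained iff exon count ≥ 2, FPKM > 1, coverage > 3,
length ≥ 200 nt (inclusive), coding-potential score < 0, and it has no
homology hit with alignment length > 30 bp at e-value < 10⁻³. Thresholds
are applied per transcript; the homology rule additionally acts at locus
level — one significantly-hit transcript discredits its whole locus. The
rejection log records the first failed rule in the fixed order
exon/FPKM/coverage/length/coding-potential/homology.

Class codes relate a query to its best-matching reference transcript with
precedence `=` > `c` > `j` > `o` > `p` > `u`:

* `=` — identical intron chain (multi-exon only; two single-exon
  transcripts are never `=`);
* `c` — query contained: every query intron is a reference intron and
  every query exon base falls inside reference exons;
* `j` — at least one shared intron (splice junction) without `=`/`c`;
* `o` — ≥ 1 bp of exonic overlap without a shared junction;
* `p` — no exonic overlap but the query lies within a run-on distance
  (default 2 kb, configurable — the convention is not universal) of a
  reference transcript's end;
* `u` — none of the above (also the result against an empty reference).

Ties between references at equal precedence break by more shared
junctions, then larger exonic overlap, then lexicographic reference id,
making the assignment deterministic. A locus matches the known set iff any
member transcript scores in {=, c, j, o, p}; otherwise it is novel.

## Neighbor correlation

The closest coding gene minimizes the interval gap (0 on intersection);
ties break by smaller start then id. The signed distance is negative when
the coding gene lies 5′ of the lincRNA on the forward axis. Correlation
comparison uses Pearson coefficients of raw FPKM across all samples (the
log transform is deliberately not applied here), three pair classes at
matched counts — lincRNA/neighbor within 20 kb, consecutive coding pairs
under 20 kb apart, and seeded random coding pairs — and reports two-sided
t and Wilcoxon rank-sum p-values per class contrast. Pairs with a
zero-variance member are dropped and logged. One numerical caveat worth
recording: the sample correlation of a randomly permuted vector against a
fixed one has expectation −r/(n−1), not 0, so permutation-based null
checks in the test suite use pair counts small enough that this bias is
far below the contrast's sampling error.

## Tissue specificity

τ = Σᵢ(1 − xᵢ)/(N − 1) over N ≥ 2 tissue summaries with xᵢ normalized by
the maximum; the min-ratio score is 1 − minᵢ(M(i)/E(i)) with E(i) the
tissue-i summary and M(i) the maximum over the other tissues (E(i)=0
contributes an infinite ratio; the score is clamped to [0, 1]). All-zero
genes are undefined and reported missing. The τ path summarizes each
group by its maximum FPKM (the calling rule refers to where the highest
FPKM occurs); the min-ratio path by the maximum of log₂(FPKM+1) — base
and pseudocount are our choice, consistent with the DE module, since the
convention is not fixed by the formula. Per-group means are available as
an option for both. Calling thresholds: τ ≥ 0.95 (assigned to the argmax
group), min-ratio ≥ 0.75. The fraction of min-ratio calls contained in
the τ set is reported, not asserted: containment is an empirical
observation, not an identity.

## Differential expression

Two-sided Student's t-test (equal variances; Welch optional) on
log₂(FPKM+1), BH adjustment across all tested genes, and the call rule
adjusted p < α ∧ (FC > 2 ∨ FC < 0.5) ∧ max(mean_a, mean_b) > 1, with FC
the ratio of raw mean FPKM (mean_b = 0 gives +∞, which passes the FC gate
if the floor passes). Genes constant in both groups get p = 1. Gating on
the raw p-value is available (`adjust=False` / `--no-adjust`) because the
two published descriptions of this rule differ on that point; the
adjusted gate is the default. Groups need ≥ 2 samples (error) and warn
below 4 replicates.

## Selection scan

Per-SNP F_ST is the Weir & Cockerham (1984) two-population θ̂ computed
from allele counts:

    n̄ = (n₁+n₂)/2,  p̄ = (n₁p₁+n₂p₂)/(n₁+n₂)
    s² = [n₁(p₁−p̄)² + n₂(p₂−p̄)²]/n̄
    n_c = n₁+n₂ − (n₁²+n₂²)/(n₁+n₂)
    a = (n̄/n_c)[s² − (p̄(1−p̄) − s²/2)/(n̄−1)],  b = (n̄/(n̄−1))[p̄(1−p̄) − s²/2]
    θ̂ = a/(a+b)

θ̂ = 1 at fixed differences, is slightly negative at equal frequencies
(estimator noise), and SNPs monomorphic across both populations are
missing. Hudson's estimator is available as an alternative, and the test
suite checks θ̂ against an independently coded ANOVA (mean-square)
formulation of the same algebra to 10⁻¹⁰.

Windows tile each chromosome at a fixed step (F_ST and π/Δπ: 50-kb
windows, 25-kb step; Hp: 40-kb windows with a 20-kb step — half-window,
mirroring the π convention, since no step is canonical for Hp). Window
F_ST is the unweighted mean of per-SNP values (ratio-of-sums of the θ̂
components is an option). π per population is Σ 2p(1−p)·n/(n−1) over
windowed SNPs divided by the full window length (invariant sites
included), so values are per-bp; Δπ = π_ref − π_dom. Hp uses the
domestic population's allele counts by default (sweeps under
domestication depress heterozygosity there; wild or pooled counts are
options). Windows with fewer than `min_snps` (default 10) SNPs are
missing, not zero, and excluded from ranking — this keeps single-SNP
windows out of the tails.

Top-window calling flags the ⌈0.05·W⌉ most extreme non-missing windows
per statistic; ties at the cutoff are all included. Directions are the
sweep-consistent ones: F_ST and Δπ descending, Hp ascending. A lincRNA is
a candidate if its locus overlaps any flagged window by ≥ 1 bp; the three
id sets are combined with exact set algebra whose union obeys
inclusion–exclusion by construction.

## Synthetic-data generator

The generator emulates the study design at desk scale; its defaults are
the conditions under which the package's claims are tested.

**Genome and annotation.** Two chromosomes of 5,025,000 bp — sized so
50-kb/25-kb sliding windows tile exactly 200 windows per chromosome (400
genome-wide). 200 coding and 100 lincRNA loci are placed sequentially
with random 0.5–2.5-kb gaps (a placement error names the constraint if
they cannot fit). LincRNA transcripts draw lengths log-normally around a
1-kb median with 1 + Poisson(1.6) exons (mean 2.6); coding transcripts
around a 3-kb median with 1 + Poisson(10) exons. About 30% of loci get a
second isoform. Attribute tables mimic coding-potential and protein-
homology output: lincRNAs get negative scores and no hits, coding
transcripts positive scores and strong hits. A known-lncRNA reference is
built from exact structural copies of a seeded 40% of lincRNA
transcripts, so known/novel ground truth is explicit. Single-exon and
weakly expressed transcripts arise naturally and act as filter decoys.

**Expression.** Per-gene baseline log₂ expression ~ N(3, 1), per-group
effects ~ N(0, 0.5), per-sample noise ~ N(0, 0.5), back-transformed to
FPKM (log-normal, hence never negative). Planted tissue-specific genes
(20% of lincRNAs by default) express at baseline in one tissue and
64-fold lower elsewhere. The fold default is deliberately well above the
20-fold minimum the specificity claims assume: at exactly 20-fold the
expected τ of a planted gene sits exactly on the 0.95 calling threshold
(off-tissue ratio 1/20 ⇒ τ = 0.95), so recall there is a coin flip by
construction; real tissue-specific lncRNAs are near-absent off tissue,
which the floor-level default represents. Correlated lincRNA/neighbor
pairs share a latent per-sample factor scaled to the target correlation
(0.8 by default) on the log scale; the back-transform attenuates raw-FPKM
Pearson correlation slightly, which stays within the tested tolerance.
Planted DE genes live in two extra condition groups drawn from a common
profile with no per-gene condition effect except the planted fold —
tissue groups proper carry per-gene group effects and would confound a
two-condition t-test, which is also why null-DE calibration uses these
exchangeable condition groups. `simulate_de_matrix` provides the same
model standalone for calibration at arbitrary gene counts.

**Genotypes.** Balding–Nichols: ancestral frequency ~ U(0.05, 0.95), each
population's frequency Beta-distributed around it with dispersion set by
the background F_ST (0.05 default), then binomial allele counts at 72
wild and 1404 domestic haplotypes. The 20 sweeps are 50-kb intervals on
the 25-kb window grid (each sweep is exactly one fully-contained 50-kb
scan window — the unit in which recovery is measured), spaced at least
two grid steps apart; domestic frequencies inside shift by the sweep
strength (0.9) toward fixation of the ancestral-major allele, elevating
F_ST and depressing domestic diversity and heterozygosity. At strength
1 the contained SNPs are exactly fixed. Under the neutral model the mean
per-SNP θ̂ reproduces the configured background F_ST within 0.02 at
≥ 5000 SNPs, and exactly ⌈0.05·W⌉ windows are flagged by construction of
the top-5% rule.

**GWAS table.** A configurable number of SNPs placed strictly inside
lincRNA loci (recorded as ground truth) and the rest outside any lincRNA
locus, with cycling trait labels.

**Determinism.** Every generator consumes `numpy.random.default_rng`
seeded from the configuration; identical configurations give
byte-identical output files. Sub-generators offset the seed by small
constants so the annotation, expression, genotype and GWAS streams are
independent but jointly reproducible.

**What the generator does not emulate.** No linkage disequilibrium,
recombination or coalescent structure (frequencies are independent across
SNPs); no read-level noise, library-size or gene-length biases in
expression; no overlapping or nested genes; class-code ground truth only
exercises `=`/`u` in the end-to-end pipeline (the full code set is
exercised by randomized unit tests). Passing tests therefore demonstrate
correctness of the statistics and calling rules under a clean generative
model, not robustness to alignment artifacts, batch effects or LD.

## Problem sizes and numerical choices

The bundled study conditions — 400 windows, ~10,000 SNPs, 300 loci, 50
samples, 2000-gene DE calibration with 200 null replicates — run the full
suite in well under a minute; they were chosen as the smallest sizes at
which the calibration claims (background-F_ST within 0.02, ≥ 80% sweep
recovery, DE sensitivity ≥ 0.9 at 4-fold/n=5/σ=0.5, specificity recall
≥ 0.95) have comfortable statistical margins. DE sensitivity at those
stated conditions has expectation near 0.91, so it is the one quantity
that varies visibly (≈0.86–0.94) across seeds. Ranking ties in top-window
calling, reference ties in class codes, and closest-gene ties are all
broken deterministically as described above. Degenerate inputs (all-zero
genes, monomorphic SNPs, sparse windows, zero-variance expression
vectors) are reported as missing or dropped with a log entry rather than
propagated as zeros.

## Known limitations

Headline counts from the motivating study (thousands of loci from
hundreds of transcriptomes and genomes) are not reproducible here — the
underlying raw data are unavailable — so the package's claims are
calibration and recovery on its own generative model plus the exact
in-text arithmetic (array fraction; three-set inclusion–exclusion). The
F_ST estimator choice (Weir–Cockerham vs Hudson), the Hp window step, the
Hp population, and the ranking directions for Δπ and Hp are configurable
because the originating descriptions leave them open; defaults are the
sweep-consistent, field-standard readings.
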