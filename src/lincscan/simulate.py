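"""Synthetic-data generator for every input the pipeline consumes.

The generator emulates the study design the pipeline is built for: a
compact two-chromosome genome carrying non-overlapping protein-coding and
intergenic lincRNA loci; tissue-structured log-scale expression with
planted tissue-specific genes, correlated lincRNA/neighbor pairs and
differentially expressed genes; and a two-population biallelic SNP panel
(wild reference vs domestic) with Balding-Nichols background
differentiation plus planted selective sweeps (domestic allele frequencies
pushed toward fixation, hence elevated F_ST and depressed diversity and
heterozygosity). Every planted signal is recorded in a GroundTruth object
so recovery can be measured exactly. All outputs are fully determined by
the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (ExpressionMatrix, GeneLocus, SnpGenotypePanel,
                     TranscriptModel, ValidationError)


class PlacementError(ValidationError):
    """The genome is too small to place the requested loci without overlap."""


@dataclass
class SimConfig:
    """Generator parameters; defaults are the bundled study conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    # chosen so that 50-kb windows at 25-kb step tile exactly 200 windows
    # per chromosome (400 genome-wide)
    chrom_length_bp: int = 5_025_000
    n_pc_genes: int = 200
    n_linc_genes: int = 100
    n_samples_per_group: int = 10
    n_tissue_groups: int = 5
    planted_tsi_fraction: float = 0.2
    # planted DE genes: (gene id or None = auto-pick, fold change in cond_b)
    planted_de: list = field(
        default_factory=lambda: [(None, 4.0)] * 5 + [(None, 0.25)] * 5)
    background_fst: float = 0.05
    n_sweeps: int = 20
    sweep_strength: float = 0.9
    n_ref_haplotypes: int = 72
    n_dom_haplotypes: int = 1404
    snp_density: float = 1.0  # SNPs per kb

    # expression model (log2 scale)
    expr_base_mean: float = 3.0
    expr_base_sd: float = 1.0
    expr_group_sd: float = 0.5
    expr_noise_sd: float = 0.5
    specific_fold: float = 64.0  # on/off-tissue expression ratio (>=20)
    n_correlated_pairs: int = 20
    corr_target: float = 0.8
    n_samples_per_condition: int | None = None  # defaults to samples per group

    # annotation model
    known_linc_fraction: float = 0.4  # fraction mirrored into the known set
    sweep_bp: int = 50_000
    window_grid_bp: int = 25_000

    def validate(self) -> None:
        counts = (self.n_chromosomes, self.chrom_length_bp, self.n_pc_genes + 1,
                  self.n_linc_genes + 1, self.n_samples_per_group,
                  self.n_tissue_groups)
        if any(c <= 0 for c in counts):
            raise ValidationError("all counts must be positive")
        if not 0 <= self.planted_tsi_fraction <= 1:
            raise ValidationError("planted_tsi_fraction outside [0,1]")
        if not 0 < self.background_fst < 1:
            raise ValidationError("background_fst outside (0,1)")
        if not 0 <= self.sweep_strength <= 1:
            raise ValidationError("sweep_strength outside [0,1]")
        if self.chrom_length_bp < 10 * 50_000:
            raise ValidationError("chrom_length_bp below 10x the largest window")


@dataclass
class GroundTruth:
    """Planted signals, recorded at generation time."""

    specific_genes: dict = field(default_factory=dict)  # tissue -> [gene ids]
    de_genes: dict = field(default_factory=dict)  # "a|b" -> [gene ids]
    correlated_pairs: list = field(default_factory=list)  # (linc, pc, pcc)
    sweep_intervals: list = field(default_factory=list)  # (chrom, start, end)
    gwas_in_locus_ids: list = field(default_factory=list)
    known_linc_ids: list = field(default_factory=list)
    tissue_groups: list = field(default_factory=list)
    condition_pair: tuple | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["condition_pair"] = tuple(d["condition_pair"]) if d.get(
            "condition_pair") else None
        return cls(**d)


# --- annotation -------------------------------------------------------------


def _split_exons(rng, total_len: int, n_exons: int) -> list[int]:
    min_exon = 30
    n_exons = max(1, min(n_exons, total_len // min_exon))
    extra = total_len - min_exon * n_exons
    parts = rng.multinomial(extra, np.full(n_exons, 1.0 / n_exons))
    return [min_exon + int(p) for p in parts]


def _make_transcript(rng, tid, gid, chrom, start, kind) -> TranscriptModel:
    if kind == "linc":
        length = int(np.clip(rng.lognormal(math.log(1000), 0.35), 200, 20_000))
        n_exons = 1 + rng.poisson(1.6)
        intron_hi = 1500
        fpkm = float(rng.lognormal(math.log(3), 0.8))
        cov = float(rng.lognormal(math.log(10), 0.6))
    else:
        length = int(np.clip(rng.lognormal(math.log(3000), 0.5), 300, 50_000))
        n_exons = 1 + rng.poisson(10)
        intron_hi = 2000
        fpkm = float(rng.lognormal(math.log(15), 1.0))
        cov = float(rng.lognormal(math.log(40), 0.6))
    sizes = _split_exons(rng, length, n_exons)
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        exons.append((pos, pos + size))
        pos += size
        if i < len(sizes) - 1:
            pos += int(rng.integers(60, intron_hi))
    strand = "+" if rng.random() < 0.5 else "-"
    return TranscriptModel(id=tid, chrom=chrom, strand=strand, exons=exons,
                           fpkm=fpkm, coverage=cov, gene_id=gid)


def generate_annotation(config: SimConfig
                        ) -> tuple[list[GeneLocus], list[TranscriptModel]]:
    """Non-overlapping protein-coding and intergenic lincRNA loci.

    LincRNA transcripts are drawn around a 1-kb median length and ~2.6 mean
    exons; protein-coding transcripts around a 3-kb median with ~11 exons.
    Raises PlacementError when the genome cannot host the requested loci
    without overlap.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    kinds = (["pc"] * config.n_pc_genes) + (["linc"] * config.n_linc_genes)
    rng.shuffle(kinds)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom: dict[str, list[str]] = {c: [] for c in chroms}
    for i, k in enumerate(kinds):
        per_chrom[chroms[i % len(chroms)]].append(k)

    loci: list[GeneLocus] = []
    transcripts: list[TranscriptModel] = []
    n_linc_seen = 0
    n_pc_seen = 0
    min_gap = 500
    for chrom in chroms:
        pos = 0
        chrom_items = per_chrom[chrom]
        for kind in chrom_items:
            if kind == "linc":
                n_linc_seen += 1
                gid = f"linc_{n_linc_seen:05d}"
                biotype = "lincRNA_candidate"
            else:
                n_pc_seen += 1
                gid = f"pc_{n_pc_seen:05d}"
                biotype = "protein_coding"
            gap = min_gap + int(rng.integers(0, 4 * min_gap))
            start = pos + gap
            n_tx = 1 + int(rng.random() < 0.3)
            tx_group = []
            for j in range(n_tx):
                tx = _make_transcript(rng, f"{gid}.t{j + 1}", gid, chrom,
                                      start, kind)
                tx_group.append(tx)
            end = max(t.end for t in tx_group)
            if end > config.chrom_length_bp:
                raise PlacementError(
                    f"genome too small: locus {gid} would end at {end} bp on "
                    f"{chrom} (chrom_length_bp={config.chrom_length_bp}); "
                    "loci must not overlap or exceed the chromosome"
                )
            loci.append(GeneLocus(id=gid, chrom=chrom, start=start, end=end,
                                  biotype=biotype,
                                  transcript_ids=[t.id for t in tx_group]))
            transcripts.extend(tx_group)
            pos = end
    return loci, transcripts


def generate_known_reference(config: SimConfig, loci: list[GeneLocus],
                             transcripts: list[TranscriptModel]
                             ) -> tuple[list[TranscriptModel], list[str]]:
    """A known-lncRNA reference: exact structural copies of a seeded subset
    of the generated lincRNA transcripts (those loci are the planted
    known-matching set; the remainder are planted novel)."""
    rng = np.random.default_rng(config.seed + 1)
    linc_loci = [l for l in loci if l.biotype == "lincRNA_candidate"]
    k = int(round(config.known_linc_fraction * len(linc_loci)))
    chosen = sorted(rng.choice(len(linc_loci), size=k, replace=False)) if k else []
    chosen_ids = [linc_loci[i].id for i in chosen]
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    ref = []
    for n, gid in enumerate(chosen_ids, 1):
        for j, t in enumerate(by_gene[gid], 1):
            ref.append(TranscriptModel(
                id=f"known_{n:05d}.t{j}", chrom=t.chrom, strand=t.strand,
                exons=list(t.exons), fpkm=0.0, coverage=0.0,
                gene_id=f"known_{n:05d}"))
    return ref, chosen_ids


def generate_attribute_tables(config: SimConfig,
                              transcripts: list[TranscriptModel]
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coding-potential scores and homology hits standing in for CPC and
    BLASTx output: negative scores and no significant hits for lincRNA
    transcripts, positive scores and strong hits for coding ones."""
    rng = np.random.default_rng(config.seed + 2)
    scores, hits = [], []
    for t in transcripts:
        is_linc = t.gene_id.startswith("linc_")
        if is_linc:
            score = float(rng.uniform(-3.0, -0.2))
        else:
            score = float(rng.uniform(0.5, 5.0))
            hits.append({"transcript_id": t.id,
                         "aln_len": int(rng.integers(60, 400)),
                         "evalue": float(10 ** rng.uniform(-60, -10))})
        scores.append({"transcript_id": t.id, "score": score})
        t.cpc_score = score
        t.homology_hits = [(h["aln_len"], h["evalue"]) for h in hits
                           if h["transcript_id"] == t.id]
    return (pd.DataFrame(scores, columns=["transcript_id", "score"]),
            pd.DataFrame(hits, columns=["transcript_id", "aln_len", "evalue"]))


# --- expression -------------------------------------------------------------


def generate_expression(config: SimConfig, loci: list[GeneLocus]
                        ) -> tuple[ExpressionMatrix, GroundTruth]:
    """Tissue-structured FPKM matrix with planted signals.

    Baseline per-gene log2 expression ~ N(base_mean, base_sd) with per-group
    effects ~ N(0, group_sd) and per-sample noise ~ N(0, noise_sd),
    back-transformed to FPKM. Planted tissue-specific genes express at their
    baseline in one tissue and `specific_fold` lower elsewhere (>=20-fold by
    default; a non-finite fold silences off-tissue expression entirely).
    Planted correlated lincRNA/neighbor pairs share a latent sample factor
    scaled to the target Pearson correlation. Planted DE genes live in two
    extra condition groups (cond_a, cond_b) drawn from a common profile so
    that unplanted genes are exchangeable between conditions.
    """
    if not loci:
        raise ValidationError("annotation is empty")
    if config.n_samples_per_group < 2:
        raise ValidationError("need >=2 samples per group")
    rng = np.random.default_rng(config.seed + 3)
    genes = [l.id for l in loci]
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    groups = [f"tissue_{i + 1}" for i in range(config.n_tissue_groups)]
    nspg = config.n_samples_per_group

    truth = GroundTruth(tissue_groups=list(groups))

    base = rng.normal(config.expr_base_mean, config.expr_base_sd, n_genes)
    group_eff = rng.normal(0.0, config.expr_group_sd,
                           (n_genes, len(groups)))

    linc_ids = [l.id for l in loci if l.biotype == "lincRNA_candidate"]
    n_specific = int(round(config.planted_tsi_fraction * len(linc_ids)))
    specific_ids = list(rng.choice(linc_ids, size=n_specific, replace=False)) \
        if n_specific else []
    specific_tissue = {g: groups[i % len(groups)]
                       for i, g in enumerate(specific_ids)}
    for g, t in specific_tissue.items():
        truth.specific_genes.setdefault(t, []).append(g)

    # correlated lincRNA/closest-coding pairs, excluding planted-specific genes
    from .neighbors import closest_gene  # local import to avoid a cycle
    pc_loci = [l for l in loci if l.biotype == "protein_coding"]
    taken = set(specific_ids)
    corr_pairs = []
    for lid in linc_ids:
        if len(corr_pairs) >= config.n_correlated_pairs:
            break
        if lid in taken:
            continue
        pair = closest_gene(next(l for l in loci if l.id == lid), pc_loci)
        if pair.unpaired or pair.pc_gene_id in taken:
            continue
        corr_pairs.append((lid, pair.pc_gene_id))
        taken.add(lid)
        taken.add(pair.pc_gene_id)
    truth.correlated_pairs = [(a, b, config.corr_target) for a, b in corr_pairs]

    cols, labels = [], []
    data = np.empty((n_genes, 0))
    blocks = []
    corr_sd = 1.0  # log2-scale sd of the shared-factor model
    for gi, grp in enumerate(groups):
        log2x = (base[:, None] + group_eff[:, gi][:, None]
                 + rng.normal(0, config.expr_noise_sd, (n_genes, nspg)))
        # tissue-specific genes: baseline in their tissue, floor elsewhere
        for g in specific_ids:
            i = gene_idx[g]
            on = max(base[i], 2.0)  # keep planted genes clearly expressed
            if grp == specific_tissue[g]:
                mu = on
            elif np.isfinite(config.specific_fold):
                mu = on - math.log2(config.specific_fold)
            else:
                log2x[i, :] = -np.inf
                continue
            log2x[i, :] = mu + rng.normal(0, config.expr_noise_sd, nspg)
        # correlated pairs: shared latent factor at the target correlation
        rho = config.corr_target
        for a, b in corr_pairs:
            ia, ib = gene_idx[a], gene_idx[b]
            z = rng.normal(0, 1, nspg)
            ea = rng.normal(0, 1, nspg)
            log2x[ia, :] = base[ia] + corr_sd * z
            log2x[ib, :] = (base[ib]
                            + corr_sd * (rho * z + math.sqrt(1 - rho**2) * ea))
        blocks.append(np.exp2(log2x))
        cols += [f"{grp}_s{j + 1}" for j in range(nspg)]
        labels += [grp] * nspg

    # condition groups for planted differential expression
    if config.planted_de:
        npc = config.n_samples_per_condition or nspg
        if npc < 2:
            raise ValidationError("need >=2 samples per condition")
        de_ids = []
        avail = [g for g in genes if g not in taken and g not in set(specific_ids)]
        ai = 0
        planted: list[tuple[str, float]] = []
        for gid, fold in config.planted_de:
            if gid is None:
                gid = avail[ai]
                ai += 1
            if gid not in gene_idx:
                raise ValidationError(f"planted DE gene {gid!r} not in annotation")
            planted.append((gid, float(fold)))
            de_ids.append(gid)
        for cond in ("cond_a", "cond_b"):
            log2x = (base[:, None]
                     + rng.normal(0, config.expr_noise_sd, (n_genes, npc)))
            if cond == "cond_b":
                for gid, fold in planted:
                    log2x[gene_idx[gid], :] += math.log2(fold)
            blocks.append(np.exp2(log2x))
            cols += [f"{cond}_s{j + 1}" for j in range(npc)]
            labels += [cond] * npc
        truth.de_genes["cond_a|cond_b"] = de_ids
        truth.condition_pair = ("cond_a", "cond_b")

    data = np.concatenate(blocks, axis=1)
    values = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"),
                          columns=cols)
    matrix = ExpressionMatrix(values, pd.Series(labels, index=cols, name="group"))
    return matrix, truth


def simulate_de_matrix(n_genes: int, n_planted: int, fold: float,
                       n_per_group: int, sigma: float, seed: int,
                       base_mean: float = 3.0, base_sd: float = 1.0
                       ) -> tuple[ExpressionMatrix, list[str]]:
    """Two-condition matrix for differential-expression calibration: null
    genes share one profile across conditions; the first `n_planted` genes
    carry `fold` in cond_b. Returns (matrix, planted gene ids)."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    base = rng.normal(base_mean, base_sd, n_genes)
    la = base[:, None] + rng.normal(0, sigma, (n_genes, n_per_group))
    lb = base[:, None] + rng.normal(0, sigma, (n_genes, n_per_group))
    planted = genes[:n_planted]
    lb[:n_planted, :] += math.log2(fold)
    data = np.exp2(np.concatenate([la, lb], axis=1))
    cols = ([f"cond_a_s{i + 1}" for i in range(n_per_group)]
            + [f"cond_b_s{i + 1}" for i in range(n_per_group)])
    labels = ["cond_a"] * n_per_group + ["cond_b"] * n_per_group
    matrix = ExpressionMatrix(
        pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), columns=cols),
        pd.Series(labels, index=cols, name="group"))
    return matrix, planted


# --- genotypes --------------------------------------------------------------


def generate_genotypes(config: SimConfig
                       ) -> tuple[SnpGenotypePanel, GroundTruth]:
    """Two-population allele-count panel with planted sweeps.

    Neutral SNPs: ancestral frequency ~ U(0.05, 0.95); each population's
    frequency ~ Beta with dispersion set from background_fst (Balding-
    Nichols); allele counts binomial at the sampled haplotype numbers.
    SNPs inside sweep intervals have the domestic frequency shifted by
    sweep_strength toward fixation of the ancestral-major allele.
    """
    config.validate()
    if config.n_ref_haplotypes <= 0 or config.n_dom_haplotypes <= 0:
        raise ValidationError("both populations need >0 haplotypes")
    rng = np.random.default_rng(config.seed + 4)
    truth = GroundTruth()
    fst = config.background_fst
    grid = config.window_grid_bp

    # sweep placement on the window grid, spread across chromosomes,
    # spaced >= 2 windows apart so flanking windows never span two sweeps
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    if config.n_sweeps:
        candidates = []
        for chrom in chroms:
            starts = np.arange(2 * grid, config.chrom_length_bp
                               - config.sweep_bp - 2 * grid, grid)
            candidates += [(chrom, int(s)) for s in starts]
        chosen: list[tuple[str, int]] = []
        order = rng.permutation(len(candidates))
        for i in order:
            chrom, s = candidates[i]
            if all(c != chrom or abs(s - t) >= config.sweep_bp + 2 * grid
                   for c, t in chosen):
                chosen.append((chrom, s))
            if len(chosen) == config.n_sweeps:
                break
        if len(chosen) < config.n_sweeps:
            raise PlacementError("genome too small for the requested sweeps")
        truth.sweep_intervals = sorted(
            (c, s, s + config.sweep_bp) for c, s in chosen)

    frames = []
    for chrom in chroms:
        n_snps = int(round(config.chrom_length_bp / 1000 * config.snp_density))
        pos = np.sort(rng.choice(config.chrom_length_bp, size=n_snps,
                                 replace=False)) + 1  # 1-based
        p_anc = rng.uniform(0.05, 0.95, n_snps)
        a = p_anc * (1 - fst) / fst
        b = (1 - p_anc) * (1 - fst) / fst
        p_ref = rng.beta(a, b)
        p_dom = rng.beta(a, b)
        for c, s, e in truth.sweep_intervals:
            if c != chrom:
                continue
            inside = (pos > s) & (pos <= e)
            target = (p_anc >= 0.5).astype(float)
            p_dom = np.where(inside,
                             p_dom + config.sweep_strength * (target - p_dom),
                             p_dom)
        c_ref = rng.binomial(config.n_ref_haplotypes, p_ref)
        c_dom = rng.binomial(config.n_dom_haplotypes, p_dom)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "n_ref": config.n_ref_haplotypes, "c_ref": c_ref,
            "n_dom": config.n_dom_haplotypes, "c_dom": c_dom,
        }))
    panel = SnpGenotypePanel(pd.concat(frames, ignore_index=True))
    return panel, truth


# --- GWAS table -------------------------------------------------------------

TRAITS = ("comb_size", "egg_weight", "body_weight", "growth_rate",
          "disease_resistance")


def generate_gwas_table(config: SimConfig, loci: list[GeneLocus],
                        n_snps: int = 60, n_in_locus: int = 10
                        ) -> tuple[pd.DataFrame, GroundTruth]:
    """GWAS significant-SNP table with `n_in_locus` SNPs planted strictly
    inside lincRNA loci (recorded in GroundTruth) and the rest outside any
    lincRNA locus."""
    linc = [l for l in loci if l.biotype == "lincRNA_candidate"]
    if n_snps and not linc:
        raise ValidationError("annotation has no lincRNA loci")
    if n_in_locus > n_snps:
        raise ValidationError("n_in_locus exceeds n_snps")
    footprint = sum(l.end - l.start for l in linc)
    if n_in_locus > footprint:
        raise PlacementError(
            f"requested {n_in_locus} in-locus SNPs but lincRNA loci cover "
            f"only {footprint} bp")
    rng = np.random.default_rng(config.seed + 5)
    truth = GroundTruth()
    rows = []
    used: set[tuple[str, int]] = set()
    k = 0
    while k < n_in_locus:
        locus = linc[int(rng.integers(len(linc)))]
        # 1-based position strictly inside [start, end): start < pos <= end
        p = int(rng.integers(locus.start + 1, locus.end + 1))
        if (locus.chrom, p) in used:
            continue
        used.add((locus.chrom, p))
        k += 1
        sid = f"gwas_{k:04d}"
        rows.append({"snp_id": sid, "chrom": locus.chrom, "pos": p,
                     "trait": TRAITS[k % len(TRAITS)]})
        truth.gwas_in_locus_ids.append(sid)
    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in linc:
        by_chrom.setdefault(l.chrom, []).append(l)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    while k < n_snps:
        chrom = chroms[int(rng.integers(len(chroms)))]
        p = int(rng.integers(1, config.chrom_length_bp + 1))
        if any(l.start < p <= l.end for l in by_chrom.get(chrom, ())):
            continue
        if (chrom, p) in used:
            continue
        used.add((chrom, p))
        k += 1
        rows.append({"snp_id": f"gwas_{k:04d}", "chrom": chrom, "pos": p,
                     "trait": TRAITS[k % len(TRAITS)]})
    table = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "trait"])
    return table, truth


def merge_truths(*truths: GroundTruth) -> GroundTruth:
    out = GroundTruth()
    for t in truths:
        for k, v in t.specific_genes.items():
            out.specific_genes.setdefault(k, []).extend(v)
        for k, v in t.de_genes.items():
            out.de_genes.setdefault(k, []).extend(v)
        out.correlated_pairs += t.correlated_pairs
        out.sweep_intervals += t.sweep_intervals
        out.gwas_in_locus_ids += t.gwas_in_locus_ids
        out.known_linc_ids += t.known_linc_ids
        if t.tissue_groups:
            out.tissue_groups = t.tissue_groups
        if t.condition_pair:
            out.condition_pair = t.condition_pair
    return out
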