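"""Closest protein-coding gene assignment and neighbor-expression correlation.

For each lincRNA locus we find the protein-coding gene minimizing the
interval gap (0 when the intervals intersect) and report a signed distance
with respect to the forward genome axis: negative when the coding gene lies
5' (lower coordinates) of the lincRNA. Correlations are Pearson coefficients
of raw FPKM across all samples, compared between three matched-size pair
classes: lincRNA-neighbor, adjacent coding-coding, and random coding pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionMatrix, GeneLocus, ValidationError


@dataclass(frozen=True)
class NeighborPair:
    linc_id: str
    pc_gene_id: str | None
    signed_distance: int | None  # None when no coding gene shares the chromosome

    @property
    def unpaired(self) -> bool:
        return self.pc_gene_id is None


def _gap_and_sign(linc: GeneLocus, gene: GeneLocus) -> int:
    if linc.overlaps(gene.start, gene.end):
        return 0
    if gene.end <= linc.start:  # gene 5' of the lincRNA on the forward axis
        return -(linc.start - gene.end)
    return gene.start - linc.end


def closest_gene(linc: GeneLocus, pc_genes: list[GeneLocus]) -> NeighborPair:
    """Minimal-gap coding gene; ties broken by smaller start, then id."""
    best_key = None
    best: GeneLocus | None = None
    for g in pc_genes:
        if g.chrom != linc.chrom:
            continue
        d = _gap_and_sign(linc, g)
        key = (abs(d), g.start, g.id)
        if best_key is None or key < best_key:
            best_key, best = key, g
    if best is None:
        return NeighborPair(linc.id, None, None)
    return NeighborPair(linc.id, best.id, _gap_and_sign(linc, best))


def closest_genes(lincs: list[GeneLocus], pc_genes: list[GeneLocus]
                  ) -> list[NeighborPair]:
    return [closest_gene(l, pc_genes) for l in lincs]


def pairs_to_dataframe(pairs: list[NeighborPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"linc_id": p.linc_id, "pc_gene_id": p.pc_gene_id,
          "signed_distance": p.signed_distance} for p in pairs],
        columns=["linc_id", "pc_gene_id", "signed_distance"],
    )


@dataclass
class CorrelationReport:
    """PCC distributions for the three pair classes and their contrasts."""

    pcc_linc_neighbor: np.ndarray
    pcc_pc_neighbor: np.ndarray
    pcc_random: np.ndarray
    tests: dict[str, dict[str, float]] = field(default_factory=dict)
    dropped_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pcc_linc_neighbor)


def _pcc_for_pairs(matrix: ExpressionMatrix,
                   pairs: list[tuple[str, str]]
                   ) -> tuple[np.ndarray, list[tuple[str, str]]]:
    vals = matrix.values
    out, dropped = [], []
    for a, b in pairs:
        x = vals.loc[a].to_numpy(float)
        y = vals.loc[b].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            dropped.append((a, b))
            continue
        out.append(float(np.corrcoef(x, y)[0, 1]))
    return np.asarray(out), dropped


def adjacent_pc_pairs(pc_genes: list[GeneLocus], window: int) -> list[tuple[str, str]]:
    """Consecutive coding-gene pairs (by start) closer than `window` bp."""
    pairs = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in pc_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        genes = sorted(genes, key=lambda g: (g.start, g.id))
        for a, b in zip(genes, genes[1:]):
            if max(0, b.start - a.end) <= window:
                pairs.append((a.id, b.id))
    return pairs


def correlation_comparison(
    matrix: ExpressionMatrix,
    pairs: list[NeighborPair],
    pc_genes: list[GeneLocus],
    window: int = 20_000,
    seed: int = 0,
) -> CorrelationReport:
    """Compare PCC distributions of lincRNA-neighbor pairs (|distance| <=
    window), adjacent coding pairs (< window apart), and random coding pairs,
    with matched pair counts; two-sided t and Wilcoxon rank-sum p-values per
    contrast."""
    if matrix.values.shape[1] < 3:
        raise ValidationError("need >=3 samples for correlation analysis")
    rng = np.random.default_rng(seed)

    linc_pairs = [(p.linc_id, p.pc_gene_id) for p in pairs
                  if not p.unpaired and abs(p.signed_distance) <= window
                  and p.linc_id in matrix.genes and p.pc_gene_id in matrix.genes]
    pcc_linc, dropped = _pcc_for_pairs(matrix, linc_pairs)
    n = len(pcc_linc)
    if n == 0:
        raise ValidationError("no lincRNA-neighbor pairs within the window")

    adj = [p for p in adjacent_pc_pairs(pc_genes, window)
           if p[0] in matrix.genes and p[1] in matrix.genes]
    pcc_adj, drop2 = _pcc_for_pairs(matrix, adj)
    if len(pcc_adj) >= n:
        pcc_adj = rng.choice(pcc_adj, size=n, replace=False)
    else:
        n = min(n, len(pcc_adj)) or n  # degenerate annotations: keep linc count

    pc_ids = [g.id for g in pc_genes if g.id in matrix.genes]
    rand_pairs: list[tuple[str, str]] = []
    seen = set()
    while len(rand_pairs) < n + len(drop2) + 8:  # headroom for drops
        i, j = rng.choice(len(pc_ids), size=2, replace=False)
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        rand_pairs.append((pc_ids[i], pc_ids[j]))
        if len(seen) >= len(pc_ids) * (len(pc_ids) - 1) // 2:
            break
    pcc_rand, drop3 = _pcc_for_pairs(matrix, rand_pairs)
    m = min(n, len(pcc_adj), len(pcc_rand))
    pcc_linc, pcc_adj, pcc_rand = pcc_linc[:m], pcc_adj[:m], pcc_rand[:m]

    tests = {}
    for name, (a, b) in {
        "linc_vs_random": (pcc_linc, pcc_rand),
        "linc_vs_pc_neighbor": (pcc_linc, pcc_adj),
        "pc_neighbor_vs_random": (pcc_adj, pcc_rand),
    }.items():
        t_p = stats.ttest_ind(a, b).pvalue if len(a) > 1 else np.nan
        w_p = stats.ranksums(a, b).pvalue if len(a) > 0 else np.nan
        tests[name] = {"t_pvalue": float(t_p), "wilcoxon_pvalue": float(w_p)}

    return CorrelationReport(pcc_linc, pcc_adj, pcc_rand, tests,
                             dropped + drop2 + drop3)


def expressed_pair_mask(
    matrix: ExpressionMatrix,
    pairs: list[NeighborPair],
    group: str,
    min_mean_fpkm: float = 1.0,
) -> list[NeighborPair]:
    """Pairs whose both members have mean FPKM > min_mean_fpkm in `group`
    (the rule for counting a lincRNA/neighbor pair as expressed in a tissue)."""
    samples = matrix.samples_in_group(group)
    if not samples:
        raise ValidationError(f"group {group!r} is empty or unknown")
    means = matrix.values[samples].mean(axis=1)
    kept = []
    for p in pairs:
        if p.unpaired:
            continue
        if (means.get(p.linc_id, 0.0) > min_mean_fpkm
                and means.get(p.pc_gene_id, 0.0) > min_mean_fpkm):
            kept.append(p)
    return kept
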