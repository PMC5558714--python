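"""Selection scan between a wild reference and a domestic population.

Per-SNP differentiation is measured with the Weir & Cockerham (1984)
two-population theta-hat computed from allele counts (Hudson's estimator is
available as an alternative). Windowed statistics over sliding windows:

* F_ST: mean of per-SNP values (or ratio of estimator components),
  50-kb windows by default;
* nucleotide diversity pi per population: sum over windowed SNPs of
  2p(1-p) * n/(n-1), divided by the window length (per-bp, invariant sites
  included); delta_pi = pi_ref - pi_dom, 50-kb windows / 25-kb step;
* pooled heterozygosity Hp = 2*sum(nMAJ)*sum(nMIN) / (sum(nMAJ)+sum(nMIN))^2
  over the window's SNP major/minor allele counts (domestic population by
  default), 40-kb windows.

Candidate windows are the most extreme top fraction (5%) per statistic in
its sweep direction (F_ST and delta_pi: largest; Hp: smallest); candidate
lincRNAs are loci overlapping any flagged window by >=1 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import GeneLocus, SnpGenotypePanel, ValidationError

# --- per-SNP F_ST -----------------------------------------------------------


def fst_weir_cockerham(n1, c1, n2, c2):
    """Weir & Cockerham theta-hat for two populations from allele counts.

    n1, n2: alleles sampled per population; c1, c2: counts of one allele.
    Vectorized; returns NaN for SNPs monomorphic across both populations.
    Values can be slightly negative at near-equal frequencies.
    """
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    p1 = np.asarray(c1, float) / n1
    p2 = np.asarray(c2, float) / n2
    r = 2.0
    n_bar = (n1 + n2) / r
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    pq = p_bar * (1.0 - p_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (s2 - (pq - s2 * (r - 1) / r) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (pq - s2 * (r - 1) / r)
        theta = a / (a + b)
    mono = (p_bar == 0) | (p_bar == 1)
    theta = np.where(mono, np.nan, theta)
    return theta, a, b


def fst_hudson(n1, c1, n2, c2):
    """Hudson's F_ST estimator (numerator/denominator form)."""
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    p1 = np.asarray(c1, float) / n1
    p2 = np.asarray(c2, float) / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = num / den
    return np.where(den == 0, np.nan, fst)


def fst_per_snp(panel: SnpGenotypePanel, estimator: str = "wc") -> np.ndarray:
    """Per-SNP F_ST between the two populations of the panel."""
    df = panel.snps
    if ((df["n_ref"] < 2) | (df["n_dom"] < 2)).any():
        raise ValidationError("both populations need >=2 sampled alleles per SNP")
    if estimator == "wc":
        theta, _, _ = fst_weir_cockerham(df["n_ref"], df["c_ref"],
                                         df["n_dom"], df["c_dom"])
        return theta
    if estimator == "hudson":
        return fst_hudson(df["n_ref"], df["c_ref"], df["n_dom"], df["c_dom"])
    raise ValidationError(f"unknown F_ST estimator {estimator!r}")


# --- windowed statistics ----------------------------------------------------


def _window_starts(length: int, window_bp: int, step_bp: int) -> np.ndarray:
    if length < window_bp:
        return np.array([], dtype=int)
    return np.arange(0, length - window_bp + 1, step_bp)


def window_scan(
    panel: SnpGenotypePanel,
    window_bp: int = 50_000,
    step_bp: int = 25_000,
    min_snps: int = 10,
    chrom_lengths: dict[str, int] | None = None,
    hp_population: str = "dom",
    fst_estimator: str = "wc",
    fst_mode: str = "mean",
) -> pd.DataFrame:
    """All windowed statistics over sliding windows.

    Returns a DataFrame with columns chrom, start, end, n_snps, fst,
    pi_ref, pi_dom, delta_pi, hp. Windows with fewer than `min_snps` SNPs
    have NaN statistics (excluded from ranking). Window intervals are
    0-based half-open; a SNP at 1-based position P (0-based P-1) belongs to
    windows with start <= P-1 < end.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValidationError("window_bp and step_bp must be positive")
    df = panel.snps
    theta, wc_a, wc_b = fst_weir_cockerham(df["n_ref"], df["c_ref"],
                                           df["n_dom"], df["c_dom"])
    if fst_estimator == "hudson":
        theta = fst_hudson(df["n_ref"], df["c_ref"], df["n_dom"], df["c_dom"])

    rows = []
    for chrom, grp in df.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos0 = grp["pos"].to_numpy() - 1  # 0-based
        if np.any(np.diff(pos0) <= 0):
            raise ValidationError(f"panel not sorted on {chrom}")
        length = (chrom_lengths or {}).get(chrom, int(pos0[-1]) + 1)
        n_ref = grp["n_ref"].to_numpy(float)
        c_ref = grp["c_ref"].to_numpy(float)
        n_dom = grp["n_dom"].to_numpy(float)
        c_dom = grp["c_dom"].to_numpy(float)
        p_ref = c_ref / n_ref
        p_dom = c_dom / n_dom
        site_pi_ref = 2 * p_ref * (1 - p_ref) * n_ref / (n_ref - 1)
        site_pi_dom = 2 * p_dom * (1 - p_dom) * n_dom / (n_dom - 1)
        if hp_population == "dom":
            cnt, tot = c_dom, n_dom
        elif hp_population == "ref":
            cnt, tot = c_ref, n_ref
        elif hp_population == "pooled":
            cnt, tot = c_ref + c_dom, n_ref + n_dom
        else:
            raise ValidationError(f"unknown hp_population {hp_population!r}")
        n_maj = np.maximum(cnt, tot - cnt)
        n_min = np.minimum(cnt, tot - cnt)
        th = theta[idx] if isinstance(theta, np.ndarray) else theta.loc[idx]
        th = np.asarray(th, float)
        a_arr = np.asarray(wc_a[idx] if isinstance(wc_a, np.ndarray) else wc_a.loc[idx], float)
        b_arr = np.asarray(wc_b[idx] if isinstance(wc_b, np.ndarray) else wc_b.loc[idx], float)

        for start in _window_starts(length, window_bp, step_bp):
            end = start + window_bp
            lo, hi = np.searchsorted(pos0, [start, end])
            n = hi - lo
            if n < min_snps:
                rows.append({"chrom": chrom, "start": int(start), "end": int(end),
                             "n_snps": int(n), "fst": np.nan, "pi_ref": np.nan,
                             "pi_dom": np.nan, "delta_pi": np.nan, "hp": np.nan})
                continue
            th_w = th[lo:hi]
            if fst_mode == "mean":
                fst = float(np.nanmean(th_w)) if np.any(~np.isnan(th_w)) else np.nan
            elif fst_mode == "ratio":
                a_s = np.nansum(a_arr[lo:hi])
                ab_s = np.nansum((a_arr + b_arr)[lo:hi])
                fst = float(a_s / ab_s) if ab_s != 0 else np.nan
            else:
                raise ValidationError(f"unknown fst_mode {fst_mode!r}")
            pr_ = float(site_pi_ref[lo:hi].sum() / window_bp)
            pd_ = float(site_pi_dom[lo:hi].sum() / window_bp)
            smaj = float(n_maj[lo:hi].sum())
            smin = float(n_min[lo:hi].sum())
            hp = 2 * smaj * smin / (smaj + smin) ** 2 if smaj + smin > 0 else np.nan
            rows.append({"chrom": chrom, "start": int(start), "end": int(end),
                         "n_snps": int(n), "fst": fst, "pi_ref": pr_,
                         "pi_dom": pd_, "delta_pi": pr_ - pd_, "hp": hp})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                       "fst", "pi_ref", "pi_dom", "delta_pi",
                                       "hp"])


SWEEP_DIRECTIONS = {"fst": "high", "delta_pi": "high", "hp": "low",
                    "pi_ref": "high", "pi_dom": "low"}


def call_top_windows(
    windows: pd.DataFrame,
    statistic: str,
    fraction: float = 0.05,
    direction: str | None = None,
) -> pd.Series:
    """Boolean flag per window: in the top `fraction` most extreme
    non-missing windows for `statistic` (ceil(fraction*W) windows; ties at
    the cutoff value are all included)."""
    if statistic not in windows.columns:
        raise ValidationError(f"unknown statistic {statistic!r}")
    direction = direction or SWEEP_DIRECTIONS.get(statistic, "high")
    vals = windows[statistic].to_numpy(float)
    ok = ~np.isnan(vals)
    w = int(ok.sum())
    if w == 0:
        raise ValidationError("all windows missing; nothing to rank")
    k = math.ceil(fraction * w)
    usable = vals[ok]
    order = np.sort(usable)
    cutoff = order[-k] if direction == "high" else order[k - 1]
    if direction == "high":
        flag = ok & (vals >= cutoff)
    else:
        flag = ok & (vals <= cutoff)
    return pd.Series(flag, index=windows.index, name=f"top_{statistic}")


def loci_in_candidates(
    windows: pd.DataFrame, flags: pd.Series, loci: list[GeneLocus]
) -> set[str]:
    """Ids of loci overlapping >=1 flagged window by >=1 bp."""
    flagged = windows.loc[flags.to_numpy(bool), ["chrom", "start", "end"]]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in flagged.itertuples(index=False):
        by_chrom.setdefault(chrom, []).append((int(s), int(e)))
    hit = set()
    for locus in loci:
        for s, e in by_chrom.get(locus.chrom, ()):
            if locus.start < e and s < locus.end:
                hit.add(locus.id)
                break
    return hit


@dataclass(frozen=True)
class CandidateSets:
    """Three-statistic candidate bookkeeping with exact set algebra."""

    by_fst: frozenset
    by_delta_pi: frozenset
    by_hp: frozenset

    @property
    def pairwise(self) -> dict[str, int]:
        return {
            "fst_and_delta_pi": len(self.by_fst & self.by_delta_pi),
            "fst_and_hp": len(self.by_fst & self.by_hp),
            "delta_pi_and_hp": len(self.by_delta_pi & self.by_hp),
        }

    @property
    def triple(self) -> int:
        return len(self.by_fst & self.by_delta_pi & self.by_hp)

    @property
    def union(self) -> frozenset:
        return self.by_fst | self.by_delta_pi | self.by_hp

    def summary(self) -> dict:
        pw = self.pairwise
        out = {
            "n_fst": len(self.by_fst),
            "n_delta_pi": len(self.by_delta_pi),
            "n_hp": len(self.by_hp),
            **pw,
            "all_three": self.triple,
            "union": len(self.union),
        }
        # inclusion-exclusion identity (exact by construction; kept as a
        # self-check on the bookkeeping)
        incl_excl = (out["n_fst"] + out["n_delta_pi"] + out["n_hp"]
                     - pw["fst_and_delta_pi"] - pw["fst_and_hp"]
                     - pw["delta_pi_and_hp"] + out["all_three"])
        assert incl_excl == out["union"]
        return out


def combine_candidate_sets(by_fst, by_delta_pi, by_hp) -> CandidateSets:
    return CandidateSets(frozenset(by_fst), frozenset(by_delta_pi),
                         frozenset(by_hp))
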