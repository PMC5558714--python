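"""F_ST, windowed diversity statistics, top-window calling, set algebra."""

import math

import numpy as np
import pandas as pd
import pytest

from lincscan import popgen, simulate, vcfio
from lincscan.models import GeneLocus, SnpGenotypePanel, ValidationError
from lincscan.popgen import (call_top_windows, combine_candidate_sets,
                             fst_per_snp, fst_weir_cockerham,
                             loci_in_candidates, window_scan)


def panel_from(rows):
    return SnpGenotypePanel(pd.DataFrame(
        rows, columns=["chrom", "pos", "n_ref", "c_ref", "n_dom", "c_dom"]))


def wc_anova_oracle(n1, c1, n2, c2):
    """Independent re-derivation of the two-population theta-hat via the
    ANOVA mean-square formulation."""
    p1, p2 = c1 / n1, c2 / n2
    pbar = (c1 + c2) / (n1 + n2)
    if pbar in (0.0, 1.0):
        return float("nan")
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r-1 = 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / ((n1 - 1) + (n2 - 1))
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2))  # r-1 = 1
    return (msp - msg) / (msp + (nc - 1) * msg)


class TestFstPerSnp:
    def test_fixed_difference_reaches_one(self):
        p = panel_from([("chr1", 10, 100, 100, 100, 0)])
        assert fst_per_snp(p)[0] == pytest.approx(1.0)

    def test_equal_frequencies_are_nonpositive(self):
        p = panel_from([("chr1", 10, 50, 20, 50, 20)])
        assert fst_per_snp(p)[0] <= 0

    def test_monomorphic_snp_is_missing(self):
        p = panel_from([("chr1", 10, 50, 0, 50, 0),
                        ("chr1", 20, 50, 50, 50, 50)])
        assert np.isnan(fst_per_snp(p)).all()

    def test_random_configurations_match_independent_algebra(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(50):
            n1, n2 = rng.integers(4, 300, 2)
            rows.append(("chr1", 10 * (i + 1), int(n1),
                         int(rng.integers(0, n1 + 1)), int(n2),
                         int(rng.integers(0, n2 + 1))))
        got = fst_per_snp(panel_from(rows))
        for row, val in zip(rows, got):
            expect = wc_anova_oracle(row[2], row[3], row[4], row[5])
            if math.isnan(expect):
                assert math.isnan(val)
            else:
                assert val == pytest.approx(expect, abs=1e-10)

    def test_hudson_estimator_agrees_at_fixed_difference(self):
        p = panel_from([("chr1", 10, 100, 100, 100, 0)])
        assert fst_per_snp(p, estimator="hudson")[0] == pytest.approx(1.0)

    def test_too_few_alleles_rejected(self):
        with pytest.raises(ValidationError):
            fst_per_snp(panel_from([("chr1", 10, 1, 1, 50, 20)]))


class TestWindowScan:
    def test_hand_computed_hp(self):
        # nMAJ (8, 6), nMIN (2, 4): Hp = 2*14*6/20^2 = 0.42
        p = panel_from([("chr1", 100, 10, 2, 10, 2),
                        ("chr1", 200, 10, 4, 10, 4)])
        win = window_scan(p, window_bp=1000, step_bp=1000, min_snps=1,
                          chrom_lengths={"chr1": 1000})
        assert win.loc[0, "hp"] == pytest.approx(0.42)

    def test_balanced_counts_give_hp_half(self):
        p = panel_from([("chr1", i * 10, 10, 5, 10, 5) for i in range(1, 6)])
        win = window_scan(p, window_bp=100, step_bp=100, min_snps=1,
                          chrom_lengths={"chr1": 100})
        assert win.loc[0, "hp"] == pytest.approx(0.5)

    def test_monomorphic_window_has_zero_pi(self):
        p = panel_from([("chr1", i * 10, 10, 0, 10, 10) for i in range(1, 6)])
        win = window_scan(p, window_bp=100, step_bp=100, min_snps=1,
                          chrom_lengths={"chr1": 100})
        assert win.loc[0, "pi_ref"] == 0.0
        assert win.loc[0, "pi_dom"] == 0.0
        assert win.loc[0, "hp"] == 0.0  # all SNPs fixed for the major allele

    def test_hp_bounded_and_pi_nonnegative(self, genotypes):
        panel, _ = genotypes
        win = window_scan(panel)
        ok = win.dropna()
        assert ((ok.hp >= 0) & (ok.hp <= 0.5)).all()
        assert ((ok.pi_ref >= 0) & (ok.pi_dom >= 0)).all()

    def test_sparse_window_is_missing_not_zero(self):
        p = panel_from([("chr1", 100, 10, 2, 10, 3)])
        win = window_scan(p, window_bp=1000, step_bp=1000, min_snps=2,
                          chrom_lengths={"chr1": 1000})
        assert win.loc[0, "n_snps"] == 1 and np.isnan(win.loc[0, "fst"])

    def test_every_snp_covered_by_window_over_step_windows(self, genotypes):
        panel, _ = genotypes
        window_bp, step_bp = 50_000, 25_000
        win = window_scan(panel, window_bp=window_bp, step_bp=step_bp,
                          min_snps=1,
                          chrom_lengths={"chr1": 5_025_000,
                                         "chr2": 5_025_000})
        per_window = win.groupby("chrom")["n_snps"].sum()
        df = panel.snps
        k = window_bp // step_bp
        for chrom, grp in df.groupby("chrom"):
            pos0 = grp["pos"] - 1
            interior = ((pos0 >= window_bp - step_bp)
                        & (pos0 < 5_025_000 - window_bp + step_bp))
            edge = (~interior).sum()
            # interior SNPs are counted exactly window/step times
            assert per_window[chrom] >= k * interior.sum()
            assert per_window[chrom] <= k * interior.sum() + k * edge

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValidationError):
            panel_from([("chr1", 100, 10, 2, 10, 3),
                        ("chr1", 50, 10, 2, 10, 3)])


class TestTopWindows:
    def _windows(self, values):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(len(values)) * 1000,
            "end": (np.arange(len(values)) + 1) * 1000,
            "n_snps": 10, "fst": values,
        })

    def test_exactly_five_percent_without_ties(self):
        win = self._windows(np.linspace(0, 1, 100))
        assert call_top_windows(win, "fst").sum() == 5

    def test_ties_at_cutoff_all_included(self):
        win = self._windows([0.1] * 7 + [0.9, 0.9, 0.9])
        flags = call_top_windows(win, "fst", fraction=0.2)  # k=2, 3-way tie
        assert flags.sum() == 3

    def test_low_direction_for_hp(self):
        win = self._windows([0.5] * 9 + [0.01]).rename(columns={"fst": "hp"})
        flags = call_top_windows(win, "hp", fraction=0.1)
        assert flags.tolist() == [False] * 9 + [True]

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 1, 137)
        vals[rng.choice(137, 10, replace=False)] = np.nan
        win = self._windows(vals)
        flags = call_top_windows(win, "fst", fraction=0.05)
        k = math.ceil(0.05 * np.isfinite(vals).sum())
        expect = set(pd.Series(vals).dropna().sort_values().index[-k:])
        assert set(win.index[flags]) == expect

    def test_all_missing_is_an_error(self):
        win = self._windows([np.nan] * 5)
        with pytest.raises(ValidationError):
            call_top_windows(win, "fst")


class TestLociInCandidates:
    def _flag(self, windows):
        return pd.Series([True] * len(windows), index=windows.index)

    def test_half_open_boundaries(self):
        win = pd.DataFrame({"chrom": ["chr1"], "start": [1000],
                            "end": [2000]})
        inside = GeneLocus(id="in", chrom="chr1", start=1500, end=1600,
                           biotype="lincRNA_candidate")
        past = GeneLocus(id="out", chrom="chr1", start=2000, end=2100,
                         biotype="lincRNA_candidate")
        got = loci_in_candidates(win, self._flag(win), [inside, past])
        assert got == {"in"}

    def test_matches_brute_force_overlap_scan(self):
        rng = np.random.default_rng(2)
        win = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 50),
            "start": rng.integers(0, 100_000, 50)})
        win["end"] = win["start"] + 5000
        flags = pd.Series(rng.random(50) < 0.5, index=win.index)
        loci = []
        for i in range(100):
            s = int(rng.integers(0, 105_000))
            loci.append(GeneLocus(id=f"l{i}",
                                  chrom=str(rng.choice(["chr1", "chr2"])),
                                  start=s, end=s + int(rng.integers(100, 3000)),
                                  biotype="lincRNA_candidate"))
        got = loci_in_candidates(win, flags, loci)
        expect = set()
        for l in loci:
            for _, w in win[flags].iterrows():
                if w.chrom == l.chrom and l.start < w.end and w.start < l.end:
                    expect.add(l.id)
        assert got == expect


class TestCandidateSets:
    def test_disjoint_sets_union_is_sum(self):
        s = combine_candidate_sets({"a"}, {"b"}, {"c"})
        assert s.summary()["union"] == 3 and s.triple == 0

    def test_random_sets_match_direct_union(self):
        rng = np.random.default_rng(4)
        ids = [f"l{i}" for i in range(200)]
        a, b, c = (set(rng.choice(ids, rng.integers(10, 150), replace=False))
                   for _ in range(3))
        s = combine_candidate_sets(a, b, c)
        assert s.union == frozenset(a | b | c)
        assert s.summary()["union"] == len(a | b | c)


class TestSweepRecovery:
    def test_planted_sweeps_flagged_by_fst_and_hp(self, genotypes):
        """>=80% of fully-contained sweep windows flagged by the top-5% rule
        for both F_ST (50-kb windows) and Hp (40-kb windows)."""
        panel, truth = genotypes
        lengths = {"chr1": 5_025_000, "chr2": 5_025_000}
        win = window_scan(panel, chrom_lengths=lengths)
        hpw = window_scan(panel, window_bp=40_000, step_bp=20_000,
                          chrom_lengths=lengths)
        for windows, stat in ((win, "fst"), (hpw, "hp")):
            flags = call_top_windows(windows, stat)
            hit = tot = 0
            for chrom, s, e in truth.sweep_intervals:
                sel = ((windows.chrom == chrom) & (windows.start >= s)
                       & (windows.end <= e))
                tot += int(sel.sum())
                hit += int(flags[sel].sum())
            assert tot >= len(truth.sweep_intervals) // 2
            assert hit / tot >= 0.8, stat

    def test_neutral_panel_mean_fst_matches_configuration(self):
        cfg = simulate.SimConfig(seed=13, n_sweeps=0)
        panel, _ = simulate.generate_genotypes(cfg)
        assert len(panel) >= 5000
        assert abs(np.nanmean(fst_per_snp(panel)) - 0.05) < 0.02

    def test_neutral_false_flag_fraction_is_five_percent_by_construction(self):
        cfg = simulate.SimConfig(seed=13, n_sweeps=0)
        panel, _ = simulate.generate_genotypes(cfg)
        win = window_scan(panel, chrom_lengths={"chr1": 5_025_000,
                                                "chr2": 5_025_000})
        flags = call_top_windows(win, "fst")
        w = win["fst"].notna().sum()
        assert flags.sum() == math.ceil(0.05 * w)


class TestVcfRoundTrip:
    def test_panel_survives_vcf_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        rows = [("chr1", int(10 + 7 * i), 8, int(rng.integers(0, 9)), 12,
                 int(rng.integers(0, 13))) for i in range(30)]
        panel = panel_from(rows)
        path = tmp_path / "panel.vcf"
        vcfio.write_vcf(panel, path)
        back = vcfio.read_panel_vcf(path)
        pd.testing.assert_frame_equal(back.snps, panel.snps,
                                      check_dtype=False)
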