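"""Site filtering, window scanning, Fisher testing, gDMR calling, profiles."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridase.methylation import (call_gdmrs, merge_intervals,
                                   metagene_profile, overlap_aseg_gdmr,
                                   site_filter, window_fisher, window_scan)


def _sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "allele", "count_methylated",
                                       "count_total"])


class TestSiteFilter:
    @pytest.mark.parametrize("total,kept", [(5, True), (4, False),
                                            (30, True)])
    def test_five_read_boundary(self, total, kept):
        sites = _sites([("chr1", 10, "+", "CG", "A", 1, total)])
        assert (len(site_filter(sites)) == 1) is kept

    def test_empty_input(self):
        assert site_filter(_sites([])).empty


def uniform_sites(n=60, spacing=20, depth=20, level_a=0.5, level_b=0.5,
                  context="CG"):
    rows = []
    for i in range(n):
        pos = (i + 1) * spacing
        rows.append(("chr1", pos, "+", context, "Mo17",
                     int(round(level_a * depth)), depth))
        rows.append(("chr1", pos, "+", context, "CAU5",
                     int(round(level_b * depth)), depth))
    return _sites(rows)


class TestWindowScan:
    def test_six_sites_per_allele_kept_five_dropped(self):
        for n, expect in ((6, 1), (5, 0)):
            rows = []
            for i in range(n):
                pos = 1 + i * 30  # all inside [1, 200]
                rows.append(("chr1", pos, "+", "CG", "A", 3, 10))
                rows.append(("chr1", pos, "+", "CG", "B", 3, 10))
            win = window_scan(_sites(rows), "CG", window=200, step=200)
            assert len(win) == expect

    def test_uniform_tiling_shares_sites_between_windows(self):
        """Sites every 20 bp: consecutive 200/20 windows share 9/10 sites."""
        win = window_scan(uniform_sites(), "CG")
        win = win.sort_values("start").reset_index(drop=True)
        assert (win["n_sites_a"].iloc[5:-5] == 10).all()
        assert np.all(np.diff(win["start"].to_numpy()) == 20)

    def test_pooled_counts_sum_sites(self):
        win = window_scan(uniform_sites(n=10, level_a=0.5), "CG",
                          window=200, step=200)
        row = win.iloc[0]
        assert row["meth_a"] + row["unmeth_a"] == 10 * 20

    def test_context_separation(self):
        sites = pd.concat([uniform_sites(context="CG"),
                           uniform_sites(context="CHG")])
        assert (window_scan(sites, "CHG")["context"] == "CHG").all()


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p with rational arithmetic."""
    n, row, col = a + b + c + d, a + b, a + c
    denom = comb(n, row)
    p_obs = Fraction(comb(col, a) * comb(n - col, row - a), denom)
    total = Fraction(0)
    for k in range(max(0, row + col - n), min(row, col) + 1):
        p_k = Fraction(comb(col, k) * comb(n - col, row - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(total)


class TestWindowFisher:
    def test_perfectly_opposed_table(self):
        """[[20,0],[0,20]]: two equally extreme tables out of C(40,20)."""
        p = window_fisher(20, 0, 0, 20)
        assert p == pytest.approx(2 / comb(40, 20), rel=1e-9)

    def test_identical_margins_give_p_one(self):
        assert window_fisher(5, 5, 5, 5) == 1.0

    def test_all_zero_table_is_uninformative(self):
        assert window_fisher(0, 0, 0, 0) == 1.0

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b + c + d == 0 or a + b + c + d > 40:
                continue
            assert window_fisher(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12)

    def test_agrees_with_scipy(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(8)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 30, size=4)
            if a + b + c + d == 0:
                continue
            expected = fisher_exact([[a, b], [c, d]])[1]
            assert window_fisher(a, b, c, d) == pytest.approx(expected,
                                                              abs=1e-9)


class TestMergeIntervals:
    def _frame(self, spans):
        return pd.DataFrame([("chr1", "CG", "A", s, e) for s, e in spans],
                            columns=["chrom", "context", "hyper_allele",
                                     "start", "end"])

    def test_gap_within_200_merges(self):
        out = merge_intervals(self._frame([(1000, 1200), (1350, 1550)]))
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (1000, 1550)

    def test_gap_over_200_does_not_merge(self):
        out = merge_intervals(self._frame([(1000, 1200), (1451, 1650)]))
        assert len(out) == 2

    def test_idempotent(self):
        first = merge_intervals(self._frame([(1, 100), (150, 250),
                                             (900, 950)]))
        second = merge_intervals(first)
        pd.testing.assert_frame_equal(first, second)

    def test_groups_kept_separate(self):
        frame = pd.DataFrame([("chr1", "CG", "A", 100, 200),
                              ("chr1", "CG", "B", 250, 350)],
                             columns=["chrom", "context", "hyper_allele",
                                      "start", "end"])
        assert len(merge_intervals(frame)) == 2

    @given(st.lists(st.tuples(st.integers(0, 3000), st.integers(1, 400)),
                    min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=100)
    def test_order_invariant_and_idempotent(self, raw):
        spans = [(s, s + w) for s, w in raw]
        a = merge_intervals(self._frame(spans))
        b = merge_intervals(self._frame(list(reversed(spans))))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(a, merge_intervals(a))


class TestGdmrCriteria:
    def _one_region_sites(self, level_a, level_b, depth=30, n=10,
                          spacing=20):
        rows = []
        for i in range(n):
            pos = 1 + i * spacing
            rows.append(("chr1", pos, "+", "CG", "A",
                         int(round(level_a * depth)), depth))
            rows.append(("chr1", pos, "+", "CG", "B",
                         int(round(level_b * depth)), depth))
        return _sites(rows)

    def test_strong_difference_called(self):
        gd, _ = call_gdmrs(self._one_region_sites(0.85, 0.40), "CG")
        assert len(gd) == 1
        assert gd.iloc[0]["hyper_allele"] == "A"

    def test_small_difference_rejected(self):
        """Levels 0.60 vs 0.35 differ by only 0.25 <= 0.30."""
        gd, _ = call_gdmrs(self._one_region_sites(0.60, 0.35), "CG")
        assert gd.empty

    def test_low_hyper_level_rejected(self):
        """Diff 0.36 but hyper allele at 0.38 <= 0.40 in CG."""
        gd, _ = call_gdmrs(self._one_region_sites(0.38, 0.02), "CG")
        assert gd.empty

    def test_no_sites_no_calls(self):
        gd, win = call_gdmrs(_sites([]), "CG")
        assert gd.empty and win.empty


class TestGdmrRecovery:
    def test_planted_regions_recovered(self):
        """Strong-signal regime: precision and recall >= 0.9."""
        from hybridase.simulate import SimConfig, simulate

        cfg = SimConfig(n_genes=20, chrom_length=200_000,
                        methyl_region_length=100_000, planted_gdmr_count=30,
                        methyl_depth_mean=30.0, seed=11)
        res = simulate(cfg)
        for context in ("CG", "CHG"):
            gd, _ = call_gdmrs(res.methyl_sites, context)
            planted = res.truth.gdmrs[res.truth.gdmrs["context"] == context]
            recalled = sum(
                ((gd["chrom"] == p.chrom) & (gd["start"] <= p.end)
                 & (gd["end"] >= p.start)
                 & (gd["hyper_allele"] == p.hyper_allele)).any()
                for p in planted.itertuples())
            precise = sum(
                ((planted["chrom"] == g.chrom) & (planted["start"] <= g.end)
                 & (planted["end"] >= g.start)
                 & (planted["hyper_allele"] == g.hyper_allele)).any()
                for g in gd.itertuples())
            assert recalled / len(planted) >= 0.9
            assert precise / len(gd) >= 0.9

    def test_null_methylome_rarely_yields_calls(self):
        """Equal-allele methylome: 0 gDMRs at FDR<0.01 in >=95% of seeds."""
        from hybridase.simulate import SimConfig, simulate

        zero_call_seeds = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimConfig(n_genes=10, n_chromosomes=1,
                            chrom_length=100_000,
                            methyl_region_length=30_000,
                            planted_gdmr_count=0, seed=100 + seed)
            res = simulate(cfg)
            n_called = sum(len(call_gdmrs(res.methyl_sites, ctx)[0])
                           for ctx in ("CG", "CHG"))
            zero_call_seeds += n_called == 0
        assert zero_call_seeds >= 0.95 * n_seeds


class TestMetageneProfile:
    def _genes(self, strand="+"):
        return pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                             "start": [2001], "end": [2600],
                             "strand": [strand]})

    def test_uniform_levels_give_flat_profile(self):
        rows = []
        for pos in range(1, 4601, 20):
            rows.append(("chr1", pos, "+", "CG", "A", 10, 20))
            rows.append(("chr1", pos, "+", "CG", "B", 10, 20))
        prof = metagene_profile(_sites(rows), self._genes(), flank=2000)
        covered = prof["level_A"].dropna()
        assert (covered == 0.5).all()
        assert len(prof) == 100

    def test_body_bins_are_ten_bp_for_600bp_gene(self):
        """600-bp body / 60 bins = 10 bp per bin: two sites 10 bp apart in
        the body land in adjacent bins."""
        rows = [("chr1", 2001, "+", "CG", "A", 20, 20),
                ("chr1", 2011, "+", "CG", "A", 0, 20)]
        prof = metagene_profile(_sites(rows), self._genes(), flank=2000)
        assert prof.loc[20, "level_A"] == 1.0
        assert prof.loc[21, "level_A"] == 0.0

    def test_minus_strand_flips_orientation(self):
        """A methylated block at the low-coordinate end of a minus-strand
        gene is 3' and must appear in late body bins."""
        rows = [("chr1", pos, "+", "CG", "A", 20, 20)
                for pos in range(2001, 2101, 10)]
        rows += [("chr1", pos, "+", "CG", "A", 0, 20)
                 for pos in range(2501, 2601, 10)]
        prof = metagene_profile(_sites(rows), self._genes(strand="-"),
                                flank=2000)
        body = prof[prof["region"] == "body"].set_index("bin")
        early = body.loc[20:29, "level_A"].dropna()
        late = body.loc[70:79, "level_A"].dropna()
        assert (early == 0.0).all()
        assert (late == 1.0).all()

    def test_profile_conserves_counts(self):
        rows = []
        for pos in range(1, 4601, 15):
            rows.append(("chr1", pos, "+", "CG", "A", 7, 20))
        sites = _sites(rows)
        prof = metagene_profile(sites, self._genes(), flank=2000)
        in_region = sites[(sites["pos"] >= 1) & (sites["pos"] <= 4600)]
        assert prof["meth_A"].sum() == in_region["count_methylated"].sum()
        assert prof["total_A"].sum() == in_region["count_total"].sum()


class TestOverlap:
    GENES = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                          "start": [5000], "end": [8000], "strand": ["+"]})

    def _calls(self):
        return pd.DataFrame(
            [("g", "MC/CM", "endosperm", "biased", 0.001, 9, "Mo17")],
            columns=["gene_id", "hybrid", "tissue", "status", "q_value",
                     "fold_tier", "preferred_genotype"])

    def _gdmr(self, start, end):
        return pd.DataFrame([("chr1", start, end, "CG", "CAU5")],
                            columns=["chrom", "start", "end", "context",
                                     "hyper_allele"])

    def test_one_bp_overlap_counts(self):
        ov = overlap_aseg_gdmr(self._calls(), self._gdmr(7900, 8100),
                               self.GENES)
        assert len(ov) == 1
        assert ov.iloc[0]["preferred_genotype"] == "Mo17"
        assert ov.iloc[0]["hyper_allele"] == "CAU5"

    def test_adjacent_interval_does_not_overlap(self):
        ov = overlap_aseg_gdmr(self._calls(), self._gdmr(8001, 8100),
                               self.GENES)
        assert ov.empty

    def test_chromosome_mismatch_rejected(self):
        bad = self._gdmr(7900, 8100)
        bad["chrom"] = "scaffold9"
        with pytest.raises(ValueError, match="scaffold9"):
            overlap_aseg_gdmr(self._calls(), bad, self.GENES)

    def test_planted_gdmr_inside_aseg_recovered(self, small_sim):
        """Truth-set check: a planted gDMR placed inside a gene span is
        reported for that gene when the gene is called biased."""
        gd = small_sim.truth.gdmrs.iloc[[0]]
        region_genes = small_sim.genes[
            (small_sim.genes["chrom"] == gd.iloc[0]["chrom"])]
        host = pd.DataFrame({
            "gene_id": ["host"], "chrom": gd["chrom"].values,
            "start": gd["start"].values - 50, "end": gd["end"].values + 50,
            "strand": ["+"]})
        calls = pd.DataFrame(
            [("host", "MC/CM", "endosperm", "biased", 0.001, 9, "Mo17")],
            columns=["gene_id", "hybrid", "tissue", "status", "q_value",
                     "fold_tier", "preferred_genotype"])
        ov = overlap_aseg_gdmr(calls, gd, host)
        assert len(ov) == 1
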