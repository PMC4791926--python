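"""Tier splitting, peak-to-tier assignment, and the three association
statistics (trend chi-square, Fisher low-vs-high, Pearson r)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hydromark.annotation import FEATURES
from hydromark.expression import (
    assign_peaks_to_tiers,
    association_table,
    fisher_low_vs_high,
    pearson_tier_correlation,
    tier_split,
    trend_test,
)
from hydromark.intervals import GenomicInterval, PeakSet, nearest_tss

from conftest import random_peakset


class TestTierSplit:
    def test_even_split(self):
        s = pd.Series(np.arange(9.0), index=[f"G{i}" for i in range(9)])
        t = tier_split(s)
        assert t.sizes == (3, 3, 3)
        low = set(t.assignment[t.assignment == 0].index)
        assert low == {"G0", "G1", "G2"}

    def test_remainder_goes_low(self):
        s = pd.Series(np.arange(10.0), index=[f"G{i}" for i in range(10)])
        t = tier_split(s)
        assert t.sizes == (4, 3, 3)
        assert t.tier_of("G3") == 0

    def test_all_equal_tie_by_name(self):
        s = pd.Series(1.0, index=["D", "B", "A", "C", "F", "E"])
        t = tier_split(s)
        assert list(t.assignment.index) == ["A", "B", "C", "D", "E", "F"]
        assert t.tier_of("A") == 0 and t.tier_of("F") == 2

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            tier_split(pd.Series([1.0, 2.0], index=["A", "B"]))


class TestTrendTest:
    def test_flat_proportions(self):
        r = trend_test((10, 10, 10), (100, 100, 100))
        assert r.statistic == 0.0 and r.pvalue == 1.0

    def test_all_zero_marked(self):
        assert trend_test((0, 0, 0), (50, 50, 50)).pvalue == 1.0

    def test_reversal_symmetry(self):
        a = trend_test((5, 10, 15), (100, 100, 100))
        b = trend_test((15, 10, 5), (100, 100, 100))
        assert a.pvalue == pytest.approx(b.pvalue)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.slope_sign == -b.slope_sign

    def test_against_permutation_null(self):
        """Analytic chi-square tail matches a conditional permutation null.

        The chi-square tail is asymptotic, so the comparison runs in the
        large-table regime where the lattice error of the conditional null
        is far below the Monte-Carlo resolution.
        """
        marked, totals = (600, 620, 660), (2000, 2000, 2000)
        obs = trend_test(marked, totals)
        rng = np.random.default_rng(7)
        n_perm = 20_000
        draws = np.array([
            rng.multivariate_hypergeometric(totals, sum(marked))
            for _ in range(n_perm)
        ])
        # vectorised CA statistic over draws
        s = np.arange(3.0)
        n = np.asarray(totals, float)
        N, R = n.sum(), float(sum(marked))
        num = N * draws @ s - R * (s * n).sum()
        den = R * (N - R) * (N * (s * s * n).sum() - (s * n).sum() ** 2)
        chi2 = N * num ** 2 / den
        p_perm = float((chi2 >= obs.statistic - 1e-12).mean())
        se = np.sqrt(obs.pvalue * (1 - obs.pvalue) / n_perm)
        assert abs(p_perm - obs.pvalue) <= 2 * se

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            trend_test((5, 200, 1), (100, 100, 100))


class TestFisher:
    def test_identical_rows(self):
        assert fisher_low_vs_high(5, 100, 5, 100) == 1.0

    def test_zero_margin(self):
        assert fisher_low_vs_high(0, 10, 0, 10) == 1.0

    def test_row_swap_invariance(self):
        assert fisher_low_vs_high(1, 10, 9, 10) == \
            pytest.approx(fisher_low_vs_high(9, 10, 1, 10))

    def test_against_enumeration(self):
        """Two-tailed p equals the exact-integer hypergeometric enumeration."""
        from math import comb

        m_l, t_l, m_h, t_h = 1, 10, 9, 10
        r1, c1, N = m_l + (t_l - m_l), m_l + m_h, t_l + t_h
        r1 = t_l
        lo, hi = max(0, c1 - (N - r1)), min(r1, c1)
        nums = {a: comb(r1, a) * comb(N - r1, c1 - a) for a in range(lo, hi + 1)}
        p_oracle = sum(v for v in nums.values() if v <= nums[m_l]) / comb(N, c1)
        assert fisher_low_vs_high(m_l, t_l, m_h, t_h) == pytest.approx(p_oracle, rel=1e-12)


class TestPearson:
    @pytest.mark.parametrize("counts,expected", [
        ((1, 2, 3), 1.0),
        ((3, 2, 1), -1.0),
        ((1, 3, 1), 0.0),
    ])
    def test_examples(self, counts, expected):
        r, flat = pearson_tier_correlation(counts)
        assert r == pytest.approx(expected, abs=1e-12)
        assert not flat

    def test_constant_flagged(self):
        r, flat = pearson_tier_correlation((4, 4, 4))
        assert r == 0.0 and flat


class TestAssignment:
    def _index(self):
        from hydromark.annotation import FeatureIndex, FeatureParams
        from hydromark.intervals import GeneModel

        genes = [
            GeneModel(GenomicInterval("chr1", s, s + 10_000, strand="+"),
                      gene_name=n,
                      exons=(GenomicInterval("chr1", s, s + 10_000),))
            for n, s in [("GA", 10_000), ("GB", 500_000), ("GC", 1_000_000)]
        ]
        return FeatureIndex(genes, params=FeatureParams()), genes

    def test_counts_and_gene_dedup(self):
        index, genes = self._index()
        expr = pd.Series([1.0, 5.0, 9.0], index=["GA", "GB", "GC"])
        tiers = tier_split(expr)
        # two peaks in GC's gene body (tier 2), one in GA's (tier 0)
        peaks = PeakSet([
            GenomicInterval("chr1", 1_002_000, 1_002_200),
            GenomicInterval("chr1", 1_004_000, 1_004_200),
            GenomicInterval("chr1", 12_000, 12_200),
        ])
        counts = assign_peaks_to_tiers(peaks, index, tiers)
        assert counts.peak_counts.loc["genic", 2] == 2
        assert counts.gene_counts.loc["genic", 2] == 1  # same gene twice
        assert counts.peak_counts.loc["genic", 0] == 1
        assert counts.n_excluded == 0

    def test_peak_without_expression_excluded(self):
        index, genes = self._index()
        expr = pd.Series([1.0, 5.0, 9.0], index=["GA", "GB", "GC"])
        tiers = tier_split(expr.drop("GA"), n_tiers=2)
        peaks = PeakSet([GenomicInterval("chr1", 12_000, 12_200)])
        counts = assign_peaks_to_tiers(peaks, index, tiers)
        assert counts.n_excluded == 1
        assert counts.peak_counts.values.sum() == 0

    def test_random_instance_matches_bruteforce(self, rng):
        index, genes = self._index()
        expr = pd.Series([1.0, 5.0, 9.0], index=["GA", "GB", "GC"])
        tiers = tier_split(expr)
        peaks = random_peakset(rng, 100, chroms=("chr1",), coord_max=1_200_000,
                               max_width=3_000)
        counts = assign_peaks_to_tiers(peaks, index, tiers)
        from hydromark.annotation import classify_peak

        oracle = {(f, t): 0 for f in FEATURES for t in range(3)}
        for iv in peaks:
            gene, _ = nearest_tss(iv, genes)
            t = tiers.tier_of(gene)
            for f in classify_peak(iv, index):
                oracle[(f, t)] += 1
        for f in FEATURES:
            for t in range(3):
                assert counts.peak_counts.loc[f, t] == oracle[(f, t)]


class TestAssociationTable:
    def test_direction_labels(self):
        index = TestAssignment()._index()[0]
        expr = pd.Series(np.arange(30.0), index=[f"G{i:02d}" for i in range(30)])
        tiers = tier_split(expr)
        from hydromark.expression import TierCounts

        features = list(FEATURES)
        peak_counts = pd.DataFrame(1, index=pd.Index(features, name="feature"),
                                   columns=range(3))
        gene_counts = peak_counts.copy()
        gene_counts.loc["genic"] = [0, 5, 10]
        peak_counts.loc["genic"] = [0, 5, 10]
        counts = TierCounts(peak_counts=peak_counts, gene_counts=gene_counts,
                            marked_genes={}, n_excluded=0)
        table = association_table(counts, tiers)
        assert table.loc["genic", "direction"] == "positive"
        assert table.loc["promoter", "direction"] == "none"
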