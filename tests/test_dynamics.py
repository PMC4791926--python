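"""Fate-class construction, dual-null chi-square rows, class comparison,
co-incidence, technique concordance, and the random-CpG expectation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hydromark.annotation import DYNAMICS_FEATURES, feature_distribution
from hydromark.dynamics import (
    CLASS_NAMES,
    chi2_two_cell,
    classify_dynamics,
    coincidence_regions,
    compare_dynamic_classes,
    dual_null_test,
    method_concordance,
    random_background_expectation,
)
from hydromark.intervals import GenomicInterval, PeakSet

from conftest import brute_force_pairs, random_peakset


def _ps(*spans, chrom="chr1"):
    return PeakSet([GenomicInterval(chrom, s, e) for s, e in spans])


class TestClassify:
    def test_peak_in_two_classes(self):
        hmc_n = _ps((100, 300))
        mc_c = _ps((200, 400))
        hmc_c = _ps((150, 250))
        mc_n = _ps((10_000, 10_100))
        classes = classify_dynamics(hmc_n, mc_n, hmc_c, mc_c)
        assert classes.absent.n_pairs == 1
        assert classes.retained.n_pairs == 1
        assert len(classes.gained.pairs) == 0
        # the same normal 5hmC peak sits in both classes
        assert list(classes.absent.normal_peaks) == list(classes.retained.normal_peaks)

    def test_disjoint_genomes_empty(self):
        a = _ps((0, 100))
        b = _ps((0, 100), chrom="chr9")
        classes = classify_dynamics(a, a, b, b)
        assert all(c.n_pairs == 0 for c in classes)

    def test_matches_bruteforce_oracle(self, rng):
        sets = [random_peakset(rng, 60) for _ in range(4)]
        hmc_n, mc_n, hmc_c, mc_c = sets
        classes = classify_dynamics(hmc_n, mc_n, hmc_c, mc_c)
        assert classes.absent.pairs == brute_force_pairs(hmc_n, mc_c)
        assert classes.retained.pairs == brute_force_pairs(hmc_n, hmc_c)
        assert classes.gained.pairs == brute_force_pairs(mc_n, hmc_c)
        # dedup: per-side peak sets equal unique pair participants
        assert set(classes.gained.normal_peaks) == {a for a, _ in classes.gained.pairs}
        assert set(classes.gained.cancer_peaks) == {b for _, b in classes.gained.pairs}

    def test_pair_bookkeeping_totals(self, rng):
        a = random_peakset(rng, 50)
        b = random_peakset(rng, 50)
        classes = classify_dynamics(a, a, b, b)
        per_source = {}
        for x, _ in classes.retained.pairs:
            per_source[x] = per_source.get(x, 0) + 1
        assert sum(per_source.values()) == classes.retained.n_pairs


class TestTwoCellChi2:
    def test_observed_equals_expected(self):
        chi2, p, direction = chi2_two_cell(80, 200, 0.40)
        assert chi2 == 0.0 and p == 1.0 and direction == 0

    def test_excess_value(self):
        chi2, p, direction = chi2_two_cell(120, 200, 0.40)
        expected_chi2 = (120 - 80) ** 2 / 80 + (80 - 120) ** 2 / 120
        assert chi2 == pytest.approx(expected_chi2)
        assert direction == 1
        assert p == pytest.approx(stats.chi2.sf(expected_chi2, 1))

    def test_against_binomial_simulation(self):
        """The chi-square tail matches a simulated draw-from-marginal null."""
        T, p_m, obs = 200, 0.40, 120
        chi2_obs, p_analytic, _ = chi2_two_cell(obs, T, p_m)
        rng = np.random.default_rng(11)
        draws = rng.binomial(T, p_m, size=100_000)
        e1, e2 = T * p_m, T * (1 - p_m)
        chi2_draws = (draws - e1) ** 2 / e1 + ((T - draws) - e2) ** 2 / e2
        p_sim = float((chi2_draws >= chi2_obs - 1e-12).mean())
        se = np.sqrt(max(p_analytic, 1e-6) * (1 - p_analytic) / 100_000)
        # extreme tail: simulation and analytic both effectively zero
        assert abs(p_sim - p_analytic) <= max(2 * se, 1e-4)

    def test_zero_expected_flagged(self):
        chi2, p, direction = chi2_two_cell(5, 100, 0.0)
        assert np.isinf(chi2) and p == 0.0 and direction == 1
        chi2, p, direction = chi2_two_cell(0, 100, 0.0)
        assert p == 1.0


class TestDualNull:
    def _fixture(self, rng):
        from hydromark.annotation import FeatureIndex, FeatureParams
        from hydromark.intervals import GeneModel

        genes = [
            GeneModel(GenomicInterval("chr1", s, s + 20_000, strand="+"),
                      gene_name=f"G{i}",
                      exons=(GenomicInterval("chr1", s, s + 20_000),))
            for i, s in enumerate(range(10_000, 400_000, 40_000))
        ]
        index = FeatureIndex(genes, params=FeatureParams())
        return index

    def test_bonferroni_arithmetic(self, rng):
        index = self._fixture(rng)
        hmc_n = random_peakset(rng, 80, chroms=("chr1",), coord_max=450_000,
                               max_width=2_000)
        mc_c = random_peakset(rng, 80, chroms=("chr1",), coord_max=450_000,
                              max_width=2_000)
        classes = classify_dynamics(hmc_n, hmc_n, mc_c, mc_c)
        marg = feature_distribution(hmc_n, index, features=DYNAMICS_FEATURES)
        table = dual_null_test(classes.absent, index, marg["proportion"],
                               marg["proportion"])
        assert set(table["bonferroni_m"]) == {len(DYNAMICS_FEATURES)}
        for _, row in table.iterrows():
            assert row["significant"] == (row["p"] < 0.05 / len(DYNAMICS_FEATURES))

    def test_empty_class_skipped(self, rng):
        index = self._fixture(rng)
        a = _ps((0, 100))
        b = _ps((0, 100), chrom="chr9")
        classes = classify_dynamics(a, a, b, b)
        marg = feature_distribution(a, index, features=DYNAMICS_FEATURES)
        table = dual_null_test(classes.absent, index, marg["proportion"],
                               marg["proportion"])
        assert len(table) == 0


class TestCompareClasses:
    def test_identical_proportions_p_one(self):
        in_feature = pd.DataFrame(
            {c: [50] for c in CLASS_NAMES},
            index=pd.Index(["intergenic"], name="feature"))
        out = compare_dynamic_classes(in_feature, {c: 100 for c in CLASS_NAMES},
                                      features=["intergenic"])
        assert out.loc["intergenic", "p"] == pytest.approx(1.0)

    def test_zero_class_total_errors(self):
        in_feature = pd.DataFrame({c: [5] for c in CLASS_NAMES},
                                  index=pd.Index(["genic"], name="feature"))
        with pytest.raises(ValueError, match="gained"):
            compare_dynamic_classes(in_feature,
                                    {"absent": 10, "retained": 10, "gained": 0},
                                    features=["genic"])

    def test_against_permutation(self):
        """2x3 chi-square p matches label permutation at moderate counts."""
        counts = {"absent": 50, "retained": 10, "gained": 10}
        totals = {c: 100 for c in CLASS_NAMES}
        in_feature = pd.DataFrame({c: [counts[c]] for c in CLASS_NAMES},
                                  index=pd.Index(["promoter"], name="feature"))
        out = compare_dynamic_classes(in_feature, totals, features=["promoter"])
        table = np.array([[counts[c] for c in CLASS_NAMES],
                          [totals[c] - counts[c] for c in CLASS_NAMES]])
        # permutation of class labels over pooled in/out flags
        rng = np.random.default_rng(5)
        pooled = np.repeat([1, 0], [int(table[0].sum()), int(table[1].sum())])
        obs_chi2 = stats.chi2_contingency(table, correction=False)[0]
        n_perm = 20_000
        hits = 0
        group_sizes = [totals[c] for c in CLASS_NAMES]
        for _ in range(n_perm):
            rng.shuffle(pooled)
            splits = np.split(pooled, np.cumsum(group_sizes)[:-1])
            t = np.array([[s.sum() for s in splits],
                          [len(s) - s.sum() for s in splits]])
            if (t.sum(axis=1) == 0).any():
                continue
            chi2 = stats.chi2_contingency(t, correction=False)[0]
            if chi2 >= obs_chi2 - 1e-12:
                hits += 1
        p_perm = hits / n_perm
        p = out.loc["promoter", "p"]
        se = np.sqrt(max(p, 1e-9) * (1 - p) / n_perm)
        assert abs(p_perm - p) <= max(2 * se, 1e-4)

    def test_exact_fallback_small_counts(self):
        in_feature = pd.DataFrame({"absent": [1], "retained": [0], "gained": [1]},
                                  index=pd.Index(["cgi"], name="feature"))
        out = compare_dynamic_classes(in_feature,
                                      {"absent": 5, "retained": 5, "gained": 5},
                                      features=["cgi"])
        assert bool(out.loc["cgi", "exact"])
        assert 0 < out.loc["cgi", "p"] <= 1


class TestCoincidence:
    def test_intersection_span(self, ten_gene_index):
        index, _ = ten_gene_index
        co = coincidence_regions(_ps((0, 100)), _ps((50, 150)), index)
        assert [(iv.start, iv.end) for iv in co.spans] == [(50, 100)]

    def test_abutting_not_coincident(self, ten_gene_index):
        index, _ = ten_gene_index
        co = coincidence_regions(_ps((0, 100)), _ps((100, 200)), index)
        assert len(co.spans) == 0

    def test_spans_match_bruteforce(self, ten_gene_index, rng):
        index, _ = ten_gene_index
        a = random_peakset(rng, 60)
        b = random_peakset(rng, 60)
        co = coincidence_regions(a, b, index)
        oracle = sorted(
            (x.intersection(y) for x, y in brute_force_pairs(a, b)),
            key=lambda iv: iv.sort_key())
        assert list(co.spans) == oracle


class TestConcordance:
    def test_identity_fractions_one(self, ten_gene_index, rng):
        index, _ = ten_gene_index
        peaks = random_peakset(rng, 50, chroms=("chr1", "chr2"),
                               coord_max=2_000_000)
        res = method_concordance(peaks, peaks, index)
        assert res.gene_level_fraction == 1.0
        assert res.strict_fraction == 1.0

    def test_gene_fraction_half(self, ten_gene_index):
        index, genes = ten_gene_index
        # tech1 near GA, GB, GC, GD; tech2 near GB, GC only
        tech1 = _ps((9_900, 10_100), (54_900, 55_100), (299_900, 300_100),
                    (639_900, 640_100))
        tech2 = _ps((54_000, 54_200), (301_000, 301_200))
        res = method_concordance(tech1, tech2, index)
        assert res.gene_level_fraction == pytest.approx(0.5)

    def test_strict_never_exceeds_gene_level(self, ten_gene_index, rng):
        index, _ = ten_gene_index
        for _ in range(20):
            t1 = random_peakset(rng, int(rng.integers(1, 60)),
                                chroms=("chr1", "chr2"), coord_max=2_000_000)
            t2 = random_peakset(rng, int(rng.integers(1, 60)),
                                chroms=("chr1", "chr2"), coord_max=2_000_000)
            res = method_concordance(t1, t2, index)
            assert res.strict_fraction <= res.gene_level_fraction + 1e-12

    def test_empty_tech1_errors(self, ten_gene_index):
        index, _ = ten_gene_index
        with pytest.raises(ValueError):
            method_concordance(PeakSet([]), _ps((0, 100)), index)


class TestBackgroundExpectation:
    def test_promoter_biased_peaks_significant(self, ten_gene_index, rng):
        index, genes = ten_gene_index
        # CpGs scattered uniformly; peaks piled into GA's promoter
        cpgs = PeakSet([
            GenomicInterval("chr1", int(p), int(p) + 2)
            for p in rng.integers(0, 1_000_000, size=3_000)
        ])
        peaks = PeakSet([GenomicInterval("chr1", 8_000 + 10 * i, 8_050 + 10 * i)
                         for i in range(100)])
        out = random_background_expectation(peaks, cpgs, index)
        row = out.loc["promoter"]
        assert row["direction"] == 1 and row["significant"]

    def test_empty_cpg_track_errors(self, ten_gene_index):
        index, _ = ten_gene_index
        with pytest.raises(ValueError, match="CpG"):
            random_background_expectation(_ps((0, 100)), PeakSet([]), index)

    def test_expected_proportions_match_counting_oracle(self, ten_gene_index, rng):
        from hydromark.annotation import classify_peak

        index, _ = ten_gene_index
        cpgs = PeakSet([
            GenomicInterval("chr1", int(p), int(p) + 2)
            for p in rng.integers(0, 1_000_000, size=500)
        ])
        peaks = random_peakset(rng, 40, chroms=("chr1",), coord_max=1_000_000)
        out = random_background_expectation(peaks, cpgs, index)
        for f in DYNAMICS_FEATURES:
            oracle = sum(f in classify_peak(c, index) for c in cpgs) / len(cpgs)
            assert out.loc[f, "expected_proportion"] == pytest.approx(oracle)
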