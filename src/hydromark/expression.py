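"""Expression tiers and mark-expression association statistics.

Genes are sorted by mean expression and split into ordered tiers (three by
default: low / medium / high).  Differential peaks are assigned to the tier
of their nearest-TSS gene, stratified by every feature label the peak
carries.  Three statistics summarise the association per feature: a 1-df
Cochran-Armitage chi-square for linear trend in marked-gene proportions
across tiers, Pearson's r between tier index and count, and a two-tailed
Fisher exact test comparing the low and high tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import FEATURES, FeatureIndex
from .intervals import PeakSet, TSSIndex, nearest_tss_bulk

TIER_NAMES_3 = ("low", "medium", "high")


@dataclass
class TierTable:
    """Ordered expression tiers: tier 0 holds the lowest expression."""

    assignment: pd.Series  # gene -> tier index (0-based)
    n_tiers: int
    sizes: Tuple[int, ...]
    tier_names: Tuple[str, ...]

    def tier_of(self, gene: str) -> Optional[int]:
        v = self.assignment.get(gene)
        return None if v is None else int(v)


def tier_split(expression: pd.Series, n_tiers: int = 3) -> TierTable:
    """Split genes into ``n_tiers`` contiguous blocks of sorted expression.

    Remainder genes (when N mod n_tiers != 0) go to the lower tiers; ties at
    block boundaries are broken by gene name so the split is deterministic.
    """
    expr = expression.dropna()
    n = len(expr)
    if n < n_tiers:
        raise ValueError(f"need at least {n_tiers} genes, got {n}")
    order = sorted(expr.index, key=lambda g: (expr[g], g))
    base, rem = divmod(n, n_tiers)
    sizes = tuple(base + (1 if i < rem else 0) for i in range(n_tiers))
    tiers = np.repeat(np.arange(n_tiers), sizes)
    assignment = pd.Series(tiers, index=pd.Index(order, name="gene"), name="tier")
    names = TIER_NAMES_3 if n_tiers == 3 else tuple(f"tier{i+1}" for i in range(n_tiers))
    return TierTable(assignment=assignment, n_tiers=n_tiers, sizes=sizes, tier_names=names)


@dataclass
class TierCounts:
    """Per-(feature, tier) peak counts and distinct marked-gene counts."""

    peak_counts: pd.DataFrame        # index feature, columns tier index
    gene_counts: pd.DataFrame        # index feature, columns tier index
    marked_genes: Dict[Tuple[str, int], Set[str]]
    n_excluded: int                  # peaks whose nearest gene lacks expression


def assign_peaks_to_tiers(
    peaks: PeakSet,
    index: FeatureIndex,
    tiers: TierTable,
    features: Sequence[str] = FEATURES,
) -> TierCounts:
    """Count peaks and distinct marked genes per (feature, expression tier).

    Each peak maps to its nearest-TSS gene with no distance cap (intergenic
    peaks legitimately sit >100 kb out) and is tallied in that gene's tier
    under every feature label it carries.  Peaks whose nearest gene has no
    expression value are excluded and counted in ``n_excluded``.
    """
    nt = tiers.n_tiers
    peak_counts = pd.DataFrame(0, index=pd.Index(features, name="feature"),
                               columns=range(nt))
    gene_sets: Dict[Tuple[str, int], Set[str]] = {
        (f, t): set() for f in features for t in range(nt)
    }
    names, _ = nearest_tss_bulk(peaks, index.tss_index)
    matrix = index.classify_matrix(peaks) if len(peaks) else np.zeros((0, len(FEATURES)), bool)
    col = {f: i for i, f in enumerate(FEATURES)}
    excluded = 0
    for i in range(len(peaks)):
        gene = names[i]
        tier = tiers.tier_of(gene) if gene is not None else None
        if tier is None:
            excluded += 1
            continue
        for f in features:
            if matrix[i, col[f]]:
                peak_counts.loc[f, tier] += 1
                gene_sets[(f, tier)].add(gene)
    gene_counts = pd.DataFrame(
        {t: [len(gene_sets[(f, t)]) for f in features] for t in range(nt)},
        index=pd.Index(features, name="feature"),
    )
    return TierCounts(peak_counts=peak_counts, gene_counts=gene_counts,
                      marked_genes=gene_sets, n_excluded=excluded)


@dataclass
class TrendResult:
    statistic: float
    pvalue: float
    slope_sign: int  # sign of the linear-trend numerator


def trend_test(
    marked: Sequence[int],
    totals: Sequence[int],
    scores: Optional[Sequence[float]] = None,
) -> TrendResult:
    """Cochran-Armitage chi-square for linear trend in proportions.

    Equally spaced scores (0, 1, 2, ...) by default, 1 degree of freedom, no
    continuity correction; the p-value is the upper tail of chi-square(1).
    Degenerate margins (no marked or no unmarked genes overall) return
    p = 1 by convention.
    """
    r = np.asarray(marked, dtype=float)
    n = np.asarray(totals, dtype=float)
    if np.any(r < 0) or np.any(n < r):
        raise ValueError("need 0 <= marked <= totals per tier")
    s = np.arange(len(r), dtype=float) if scores is None else np.asarray(scores, float)
    N = n.sum()
    R = r.sum()
    if R == 0 or R == N or N == 0:
        return TrendResult(0.0, 1.0, 0)
    num = N * (s * r).sum() - R * (s * n).sum()
    den = R * (N - R) * (N * (s * s * n).sum() - (s * n).sum() ** 2)
    if den <= 0:  # all weight on a single score
        return TrendResult(0.0, 1.0, 0)
    chi2 = N * num * num / den
    p = float(stats.chi2.sf(chi2, df=1))
    return TrendResult(float(chi2), p, int(np.sign(num)))


def fisher_low_vs_high(
    marked_low: int, total_low: int, marked_high: int, total_high: int
) -> float:
    """Two-tailed Fisher exact p for the low-vs-high marked-gene 2x2 table."""
    table = [
        [marked_low, total_low - marked_low],
        [marked_high, total_high - marked_high],
    ]
    if min(total_low, total_high) == 0 or (marked_low + marked_high) == 0 or (
        (total_low - marked_low) + (total_high - marked_high)
    ) == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def pearson_tier_correlation(counts: Sequence[float]) -> Tuple[float, bool]:
    """Pearson r between tier scores (0, 1, 2, ...) and counts.

    Constant counts have undefined correlation; (0.0, True) is returned with
    the flag marking the degenerate case.
    """
    c = np.asarray(counts, dtype=float)
    s = np.arange(len(c), dtype=float)
    if np.allclose(c, c[0]):
        return 0.0, True
    r = float(np.corrcoef(s, c)[0, 1])
    return r, False


def association_table(
    tier_counts: TierCounts,
    tiers: TierTable,
    alpha: float = 0.05,
    features: Sequence[str] = FEATURES,
) -> pd.DataFrame:
    """The three association statistics per feature.

    Trend and Fisher tests run on distinct marked-gene counts against tier
    sizes; Pearson's r is computed on raw peak counts (the quantity plotted
    as per-tier mark abundance).  ``direction`` is the trend sign when the
    trend is significant at ``alpha``, 'nonlinear' when the middle tier is a
    strict extremum, else 'none'.
    """
    rows = []
    totals = list(tiers.sizes)
    for f in features:
        g = [int(tier_counts.gene_counts.loc[f, t]) for t in range(tiers.n_tiers)]
        p = [int(tier_counts.peak_counts.loc[f, t]) for t in range(tiers.n_tiers)]
        tr = trend_test(g, totals)
        fi = fisher_low_vs_high(g[0], totals[0], g[-1], totals[-1])
        r, flat = pearson_tier_correlation(p)
        if tr.pvalue < alpha and tr.slope_sign != 0:
            direction = "positive" if tr.slope_sign > 0 else "negative"
        elif len(p) == 3 and (p[1] > max(p[0], p[2]) or p[1] < min(p[0], p[2])):
            direction = "nonlinear"
        else:
            direction = "none"
        rows.append({
            "feature": f,
            **{f"genes_{tiers.tier_names[t]}": g[t] for t in range(tiers.n_tiers)},
            **{f"peaks_{tiers.tier_names[t]}": p[t] for t in range(tiers.n_tiers)},
            "chi2_trend": tr.statistic,
            "p_trend": tr.pvalue,
            "pearson_r": r,
            "pearson_degenerate": flat,
            "fisher_p": fi,
            "direction": direction,
        })
    return pd.DataFrame(rows).set_index("feature")
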