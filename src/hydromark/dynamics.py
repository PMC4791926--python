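"""Cross-cell-line 5hmC fate classification and its null-model tests.

Three overlap-defined fate classes compare a normal and a cancer cell line:

* absent:   normal 5hmC peaks overlapping cancer 5mC peaks;
* retained: normal 5hmC peaks overlapping cancer 5hmC peaks;
* gained:   normal 5mC peaks overlapping cancer 5hmC peaks.

Classes are not mutually exclusive.  Each class is tested per genomic
feature against two marginal-distribution nulls — random change of the
normal-cell mark and random placement of the cancer-cell mark — via 1-df
two-cell chi-square goodness-of-fit tests with Bonferroni correction over
the features tested.  The module also provides same-cell-line 5mC/5hmC
co-incidence, concordance between two 5hmC enrichment techniques, and the
random-CpG background expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import DYNAMICS_FEATURES, FEATURES, FeatureIndex, feature_distribution
from .intervals import (
    GenomicInterval,
    PeakSet,
    TSSIndex,
    intersect_sets,
    nearest_tss_bulk,
    overlaps_any,
)

CLASS_NAMES = ("absent", "retained", "gained")


@dataclass
class OverlapClass:
    """One fate class: overlap pairs plus per-side deduplicated peaks."""

    name: str
    pairs: List[Tuple[GenomicInterval, GenomicInterval]]
    normal_peaks: PeakSet   # distinct normal-cell source peaks in the class
    cancer_peaks: PeakSet   # distinct cancer-cell partner peaks

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class DynamicsClasses:
    absent: OverlapClass
    retained: OverlapClass
    gained: OverlapClass

    def __iter__(self):
        return iter((self.absent, self.retained, self.gained))

    def __getitem__(self, name: str) -> OverlapClass:
        return {"absent": self.absent, "retained": self.retained,
                "gained": self.gained}[name]


def _overlap_class(name: str, src: PeakSet, dst: PeakSet,
                   min_overlap_bp: int = 1) -> OverlapClass:
    pairs = intersect_sets(src, dst, min_overlap_bp=min_overlap_bp)
    normal = PeakSet(sorted({a for a, _ in pairs}, key=GenomicInterval.sort_key))
    cancer = PeakSet(sorted({b for _, b in pairs}, key=GenomicInterval.sort_key))
    return OverlapClass(name=name, pairs=pairs, normal_peaks=normal, cancer_peaks=cancer)


def classify_dynamics(
    hmc_normal: PeakSet,
    mc_normal: PeakSet,
    hmc_cancer: PeakSet,
    mc_cancer: PeakSet,
    min_overlap_bp: int = 1,
) -> DynamicsClasses:
    """Build the absent / retained / gained overlap classes.

    A source peak overlapping several partner peaks counts once per class
    (the deduplicated per-side peak sets); the raw pair lists are kept for
    bookkeeping.  Classes are defined independently, so one normal 5hmC
    peak may appear in both absent and retained.
    """
    return DynamicsClasses(
        absent=_overlap_class("absent", hmc_normal, mc_cancer, min_overlap_bp),
        retained=_overlap_class("retained", hmc_normal, hmc_cancer, min_overlap_bp),
        gained=_overlap_class("gained", mc_normal, hmc_cancer, min_overlap_bp),
    )


def chi2_two_cell(observed: int, total: int, p_expected: float):
    """1-df goodness-of-fit of an in-feature count against E = total * p.

    Returns (chi2, p, direction) with direction = sign(observed - expected).
    ``p_expected`` of 0 with a positive observation is reported as p = 0.0
    (below machine floor); totals of 0 are the caller's responsibility.
    """
    if not 0.0 <= p_expected <= 1.0:
        raise ValueError("expected proportion outside [0, 1]")
    e1 = total * p_expected
    e2 = total * (1.0 - p_expected)
    direction = int(np.sign(observed - e1))
    if e1 == 0.0:
        return (np.inf, 0.0, 1) if observed > 0 else (0.0, 1.0, 0)
    if e2 == 0.0:
        return (np.inf, 0.0, -1) if observed < total else (0.0, 1.0, 0)
    chi2 = (observed - e1) ** 2 / e1 + ((total - observed) - e2) ** 2 / e2
    return float(chi2), float(stats.chi2.sf(chi2, df=1)), direction


def dual_null_test(
    oclass: OverlapClass,
    index: FeatureIndex,
    normal_marginal: pd.Series,
    cancer_marginal: pd.Series,
    features: Sequence[str] = DYNAMICS_FEATURES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test one fate class against both marginal nulls, per feature.

    ``normal_marginal`` / ``cancer_marginal`` are per-feature proportions of
    the full source peak sets (from :func:`feature_distribution`).  For each
    null the observed counts come from that side's deduplicated class peaks;
    the expectation is E = T * p(feature).  Bonferroni correction uses
    m = number of features tested.
    """
    m = len(features)
    rows = []
    for side, peaks, marginal in (
        ("normal", oclass.normal_peaks, normal_marginal),
        ("cancer", oclass.cancer_peaks, cancer_marginal),
    ):
        T = len(peaks)
        if T == 0:
            continue
        dist = feature_distribution(peaks, index, features=features)
        for f in features:
            p_f = float(marginal[f])
            obs = int(dist.loc[f, "count"])
            chi2, p, direction = chi2_two_cell(obs, T, p_f)
            rows.append({
                "class": oclass.name,
                "null_side": side,
                "feature": f,
                "observed": obs,
                "total": T,
                "expected": T * p_f,
                "chi2": chi2,
                "p": p,
                "significant": p < alpha / m,
                "direction": direction,
                "bonferroni_m": m,
            })
    return pd.DataFrame(rows)


def dynamics_table(
    classes: DynamicsClasses,
    index: FeatureIndex,
    marginals: Dict[str, pd.Series],
    features: Sequence[str] = DYNAMICS_FEATURES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full fate-class table over all three classes and both nulls.

    ``marginals`` maps 'hmc_normal', 'mc_normal', 'hmc_cancer', 'mc_cancer'
    to per-feature proportion Series of the corresponding full peak sets.
    """
    side_marginals = {
        "absent": ("hmc_normal", "mc_cancer"),
        "retained": ("hmc_normal", "hmc_cancer"),
        "gained": ("mc_normal", "hmc_cancer"),
    }
    frames = []
    for oclass in classes:
        n_key, c_key = side_marginals[oclass.name]
        frames.append(dual_null_test(
            oclass, index, marginals[n_key]["proportion"],
            marginals[c_key]["proportion"], features=features, alpha=alpha))
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _exact_2xk_p(table: np.ndarray) -> float:
    """Fisher-Freeman-Halton exact p for a 2 x k table by enumeration.

    Sums the conditional (fixed-margins) probability of every table at most
    as probable as the observed one.  Intended for small counts only.
    """
    from math import lgamma

    table = np.asarray(table, dtype=int)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    N = int(table.sum())

    def logfact(x):
        return lgamma(x + 1)

    const = sum(logfact(r) for r in row) + sum(logfact(c) for c in col) - logfact(N)

    def logp(cells_top):
        lp = const
        for j, a in enumerate(cells_top):
            lp -= logfact(a) + logfact(col[j] - a)
        return lp

    obs_lp = logp(table[0])
    total = 0.0
    k = table.shape[1]

    def rec(j, remaining, cells):
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= col[j]:
                lp = logp(cells + [remaining])
                if lp <= obs_lp + 1e-9:
                    total += np.exp(lp)
            return
        for a in range(min(col[j], remaining) + 1):
            rec(j + 1, remaining - a, cells + [a])

    rec(0, int(row[0]), [])
    return float(min(total, 1.0))


def compare_dynamic_classes(
    in_feature: pd.DataFrame,
    class_totals: Dict[str, int],
    features: Sequence[str] = DYNAMICS_FEATURES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature 2x3 chi-square comparing fate classes to each other.

    ``in_feature`` holds per-(feature, class) in-feature counts (index
    feature, columns class names).  When any expected cell drops below 1 the
    chi-square is replaced by an exact conditional test (flagged).
    """
    for cname in CLASS_NAMES:
        if class_totals.get(cname, 0) <= 0:
            raise ValueError(f"class {cname!r} has zero total regions")
    m = len(features)
    rows = []
    for f in features:
        top = np.array([int(in_feature.loc[f, c]) for c in CLASS_NAMES])
        bottom = np.array([class_totals[c] for c in CLASS_NAMES]) - top
        table = np.vstack([top, bottom])
        exact = False
        if table.sum() == 0 or (table.sum(axis=1) == 0).any():
            p = 1.0
            chi2 = 0.0
        else:
            expected = stats.contingency.expected_freq(table)
            if (expected < 1.0).any():
                p = _exact_2xk_p(table)
                chi2 = np.nan
                exact = True
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({
            "feature": f,
            **{f"in_{c}": int(t) for c, t in zip(CLASS_NAMES, top)},
            "chi2": chi2,
            "p": float(p),
            "significant": p < alpha / m,
            "exact": exact,
        })
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class CoincidenceSet:
    """Same-cell-line regions carrying both 5mC and 5hmC marks."""

    cell_line: Optional[str]
    spans: PeakSet  # intersection spans of each overlapping pair
    pairs: List[Tuple[GenomicInterval, GenomicInterval]]
    distribution: pd.DataFrame


def coincidence_regions(
    mc_set: PeakSet,
    hmc_set: PeakSet,
    index: FeatureIndex,
    cell_line: Optional[str] = None,
    min_overlap_bp: int = 1,
    features: Sequence[str] = DYNAMICS_FEATURES,
) -> CoincidenceSet:
    """Regions where a 5mC and a 5hmC peak of one cell line overlap."""
    pairs = intersect_sets(mc_set, hmc_set, min_overlap_bp=min_overlap_bp)
    spans = PeakSet([a.intersection(b) for a, b in pairs])
    dist = feature_distribution(spans, index, features=features)
    return CoincidenceSet(cell_line=cell_line, spans=spans, pairs=pairs,
                          distribution=dist)


@dataclass
class ConcordanceResult:
    gene_level_fraction: float
    strict_fraction: float            # strict genes / all tech-1 genes
    strict_fraction_of_shared: float  # strict genes / shared genes
    n_genes_tech1: int
    n_genes_shared: int
    n_genes_strict: int
    feature_comparison: pd.DataFrame


def method_concordance(
    peaks_tech1: PeakSet,
    peaks_tech2: PeakSet,
    index: FeatureIndex,
    features: Sequence[str] = DYNAMICS_FEATURES,
) -> ConcordanceResult:
    """Concordance between two 5hmC enrichment techniques.

    Gene-level fraction: of the genes nearest to tech-1 peaks, the share
    also detected by tech 2.  Strict genes are shared genes carrying a
    tech-1 peak with >= 1 bp overlap against a tech-2 peak (same-region
    detection); the strict fraction uses all tech-1 genes as denominator
    (hence is always <= the gene-level fraction) and is also reported
    relative to the shared genes.  Per-feature peak distributions of the
    two techniques are compared by two-cell chi-square.
    """
    if len(peaks_tech1) == 0:
        raise ValueError("tech-1 peak set is empty; fractions undefined")
    names1, _ = nearest_tss_bulk(peaks_tech1, index.tss_index)
    names2, _ = nearest_tss_bulk(peaks_tech2, index.tss_index)
    genes1 = {n for n in names1 if n is not None}
    genes2 = {n for n in names2 if n is not None}
    if not genes1:
        raise ValueError("no tech-1 peak maps to a gene; fractions undefined")
    shared = genes1 & genes2
    gene_fraction = len(shared) / len(genes1)

    hits = overlaps_any(peaks_tech1, peaks_tech2)
    strict_genes = {names1[i] for i in np.nonzero(hits)[0]
                    if names1[i] in shared}
    strict_fraction = len(strict_genes) / len(genes1)
    strict_of_shared = len(strict_genes) / len(shared) if shared else 0.0

    d1 = feature_distribution(peaks_tech1, index, features=features)
    d2 = feature_distribution(peaks_tech2, index, features=features)
    rows = []
    for f in features:
        chi2, p, direction = chi2_two_cell(
            int(d1.loc[f, "count"]), len(peaks_tech1), float(d2.loc[f, "proportion"]))
        rows.append({"feature": f, "tech1_prop": float(d1.loc[f, "proportion"]),
                     "tech2_prop": float(d2.loc[f, "proportion"]),
                     "chi2": chi2, "p": p, "direction": direction})
    return ConcordanceResult(
        gene_level_fraction=gene_fraction,
        strict_fraction=strict_fraction,
        strict_fraction_of_shared=strict_of_shared,
        n_genes_tech1=len(genes1),
        n_genes_shared=len(shared),
        n_genes_strict=len(strict_genes),
        feature_comparison=pd.DataFrame(rows).set_index("feature"),
    )


def random_background_expectation(
    peaks: PeakSet,
    cpg_track: PeakSet,
    index: FeatureIndex,
    features: Sequence[str] = DYNAMICS_FEATURES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Observed peak feature proportions vs. a random-CpG expectation.

    The expected proportion of peaks in a feature is the fraction of CpG
    positions falling in it (a mark scattered uniformly over CpGs).  Each
    feature gets the same two-cell chi-square as the fate-class tests.
    """
    if len(cpg_track) == 0:
        raise ValueError("empty CpG track")
    cpg_dist = feature_distribution(cpg_track, index, features=features)
    peak_dist = feature_distribution(peaks, index, features=features)
    T = len(peaks)
    m = len(features)
    rows = []
    for f in features:
        p_exp = float(cpg_dist.loc[f, "proportion"])
        obs = int(peak_dist.loc[f, "count"])
        chi2, p, direction = chi2_two_cell(obs, T, p_exp)
        rows.append({
            "feature": f, "observed": obs, "total": T,
            "expected": T * p_exp, "expected_proportion": p_exp,
            "chi2": chi2, "p": p, "significant": p < alpha / m,
            "direction": direction,
        })
    return pd.DataFrame(rows).set_index("feature")
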