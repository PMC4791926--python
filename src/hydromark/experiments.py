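"""Calibration and planted-effect recovery experiments.

These drive the synthetic generator and the statistical machinery end to
end and return summary rates:

* type-I error of the trend test under marks-independent-of-expression
  tier counts, and of the dual-null fate-class test under binomial draws
  from the reference marginal;
* recovery of planted effects — positive genic-5hmC and negative
  intergenic-5hmC expression trends, and the intergenic excess of the
  "gained" fate class — over many generator seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import DYNAMICS_FEATURES, FeatureIndex, feature_distribution
from .consensus import consensus_peaks
from .dynamics import chi2_two_cell, classify_dynamics, dual_null_test
from .expression import assign_peaks_to_tiers, tier_split, trend_test
from .io import read_expression
from .simulate import (
    SyntheticConfig,
    generate_dataset,
    simulate_null_feature_counts,
    simulate_null_tier_counts,
)


@dataclass
class CalibrationResult:
    rejection_rate: float
    nominal: float
    mc_se: float
    n_sims: int

    @property
    def within_2se(self) -> bool:
        return abs(self.rejection_rate - self.nominal) <= 2 * self.mc_se


def trend_null_calibration(
    n_sims: int = 2000,
    seed: int = 0,
    tier_totals: Sequence[int] = (100, 100, 100),
    n_marked: int = 120,
    alpha: float = 0.05,
) -> CalibrationResult:
    """Empirical type-I error of the trend test at ``alpha`` under the null.

    Marked genes are scattered over tiers independently of expression
    (multivariate hypergeometric with fixed margins — exactly the
    conditional null the Cochran-Armitage statistic addresses).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    rejections = 0
    for _ in range(n_sims):
        counts = simulate_null_tier_counts(rng, tier_totals, n_marked)
        if trend_test(counts, tier_totals).pvalue < alpha:
            rejections += 1
    rate = rejections / n_sims
    se = float(np.sqrt(alpha * (1 - alpha) / n_sims))
    return CalibrationResult(rate, alpha, se, n_sims)


def dual_null_calibration(
    n_sims: int = 2000,
    seed: int = 0,
    total: int = 400,
    proportions: Sequence[float] = (0.30, 0.45, 0.18, 0.30, 0.12, 0.15, 0.20),
    alpha: float = 0.05,
) -> CalibrationResult:
    """Type-I error of the per-feature two-cell chi-square at corrected alpha.

    In-feature counts are drawn binomially from the reference marginal (the
    test's own null); the rejection threshold is the Bonferroni-corrected
    alpha / m with m = number of features.  The rate is averaged over
    features; the MC SE accounts for per-simulation averaging across the m
    (independently drawn) feature columns.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    p = np.asarray(proportions, dtype=float)
    m = len(p)
    corrected = alpha / m
    draws = simulate_null_feature_counts(rng, total, p, size=n_sims)
    crit = stats.chi2.isf(corrected, df=1)
    e1 = total * p
    e2 = total * (1 - p)
    chi2 = (draws - e1) ** 2 / e1 + ((total - draws) - e2) ** 2 / e2
    reject = chi2 > crit
    rate = float(reject.mean())
    se = float(np.sqrt(corrected * (1 - corrected) / (n_sims * m)))
    return CalibrationResult(rate, corrected, se, n_sims * m)


@dataclass
class RecoveryResult:
    success_rate: float
    n_seeds: int
    details: pd.DataFrame


def _condition_mean_expression(dataset, condition: str) -> pd.Series:
    df = dataset.expression[condition]
    reps = [c for c in df.columns if c != "gene"]
    s = df[reps].mean(axis=1)
    s.index = df["gene"]
    return s


def trend_recovery_experiment(
    n_seeds: int = 200,
    base_seed: int = 0,
    config: Optional[SyntheticConfig] = None,
    alpha: float = 0.05,
    condition: str = "normal",
) -> Dict[str, RecoveryResult]:
    """Detection of the planted genic-positive / intergenic-negative
    5hmC-expression trends across generator seeds.

    For each seed the normal-condition 5hmC consensus peaks are assigned to
    expression tiers and the per-feature trend test is run; success means a
    significant trend of the planted sign.
    """
    cfg0 = config or SyntheticConfig()
    rows = []
    for s in range(n_seeds):
        cfg = SyntheticConfig(**{**cfg0.__dict__, "seed": base_seed + s})
        ds = generate_dataset(cfg)
        cons = consensus_peaks(ds.marks[("5hmC", condition)], k=1)
        expr = _condition_mean_expression(ds, condition)
        tiers = tier_split(expr)
        counts = assign_peaks_to_tiers(cons.peaks, ds.index, tiers)
        for feature, planted_sign in (("genic", 1), ("intergenic", -1)):
            g = [int(counts.gene_counts.loc[feature, t]) for t in range(3)]
            tr = trend_test(g, tiers.sizes)
            rows.append({
                "seed": cfg.seed, "feature": feature,
                "chi2": tr.statistic, "p": tr.pvalue, "sign": tr.slope_sign,
                "success": tr.pvalue < alpha and tr.slope_sign == planted_sign,
            })
    df = pd.DataFrame(rows)
    return {
        feature: RecoveryResult(
            success_rate=float(df[df["feature"] == feature]["success"].mean()),
            n_seeds=n_seeds,
            details=df[df["feature"] == feature].reset_index(drop=True),
        )
        for feature in ("genic", "intergenic")
    }


def gained_intergenic_recovery_experiment(
    n_seeds: int = 200,
    base_seed: int = 0,
    config: Optional[SyntheticConfig] = None,
    alpha: float = 0.05,
) -> RecoveryResult:
    """Detection of the planted intergenic excess in the "gained" class.

    The gained class (normal 5mC overlapping cancer 5hmC) is tested against
    the normal-5mC marginal; success is a Bonferroni-significant positive
    direction for the intergenic feature.
    """
    cfg0 = config or SyntheticConfig()
    rows = []
    for s in range(n_seeds):
        cfg = SyntheticConfig(**{**cfg0.__dict__, "seed": base_seed + s})
        ds = generate_dataset(cfg)
        sets = {key: consensus_peaks(reps, k=1).peaks
                for key, reps in ds.marks.items()}
        classes = classify_dynamics(
            sets[("5hmC", "normal")], sets[("5mC", "normal")],
            sets[("5hmC", "cancer")], sets[("5mC", "cancer")])
        marg_n = feature_distribution(sets[("5mC", "normal")], ds.index,
                                      features=DYNAMICS_FEATURES)["proportion"]
        marg_c = feature_distribution(sets[("5hmC", "cancer")], ds.index,
                                      features=DYNAMICS_FEATURES)["proportion"]
        table = dual_null_test(classes.gained, ds.index, marg_n, marg_c,
                               alpha=alpha)
        row = table[(table["null_side"] == "normal")
                    & (table["feature"] == "intergenic")]
        sig = bool(row["significant"].iloc[0]) if len(row) else False
        direction = int(row["direction"].iloc[0]) if len(row) else 0
        rows.append({"seed": cfg.seed, "significant": sig,
                     "direction": direction,
                     "success": sig and direction > 0})
    df = pd.DataFrame(rows)
    return RecoveryResult(success_rate=float(df["success"].mean()),
                          n_seeds=n_seeds, details=df)
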