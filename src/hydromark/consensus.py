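"""Replicate consensus peak sets and presence/absence differential regions.

Consensus regions are the merged union of all replicate peaks, retained when
at least ``k`` distinct replicates contribute an overlapping peak.  The
differential rule between two conditions is presence/absence of any overlap
between consensus regions; affinity fold-change estimation from read counts
is out of scope (peaks are the input), but a score-ratio screen over BED
score columns is offered as a coarse analogue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, PeakSet, merge_intervals, overlaps_any


@dataclass
class ConsensusSet:
    """Merged regions supported by >= min_support replicates."""

    peaks: PeakSet
    support: np.ndarray  # per-region contributing-replicate count
    min_support: int
    n_replicates: int

    def __len__(self) -> int:
        return len(self.peaks)


def consensus_peaks(replicate_sets: Sequence[PeakSet], k: int, label=None) -> ConsensusSet:
    """Regions present in at least ``k`` of the replicate peak sets.

    Candidate regions are the merged union of all replicate peaks; a region
    is retained iff peaks from >= k distinct replicates overlap it.  With a
    single replicate and k=1 this degenerates to the replicate itself
    (merged), matching single-replicate designs.
    """
    n = len(replicate_sets)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} replicates")
    union = merge_intervals(iv for rs in replicate_sets for iv in rs)
    if len(union) == 0:
        return ConsensusSet(PeakSet([], label=label), np.zeros(0, dtype=int), k, n)
    support = np.zeros(len(union), dtype=int)
    for rs in replicate_sets:
        support += overlaps_any(union, rs).astype(int)
    keep = support >= k
    kept = [iv for iv, ok in zip(union, keep) if ok]
    return ConsensusSet(PeakSet(kept, label=label), support[keep], k, n)


@dataclass
class DifferentialRegionSet:
    """Regions unique to one condition under the presence/absence rule."""

    a_unique: PeakSet
    b_unique: PeakSet
    #: regions present in both whose mean score ratio exceeded the optional
    #: threshold (empty unless score screening was requested)
    a_score_enriched: PeakSet
    b_score_enriched: PeakSet
    mark: Optional[str] = None


def _mean_scores(consensus: ConsensusSet, replicate_sets: Sequence[PeakSet]) -> np.ndarray:
    """Mean replicate peak score over each consensus region (NaN if unscored)."""
    sums = np.zeros(len(consensus.peaks))
    counts = np.zeros(len(consensus.peaks))
    for rs in replicate_sets:
        from .intervals import intersect_sets

        pos = {iv: i for i, iv in enumerate(consensus.peaks)}
        for region, peak in intersect_sets(consensus.peaks, rs):
            if peak.score is not None:
                sums[pos[region]] += peak.score
                counts[pos[region]] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def differential_regions(
    consensus_a: ConsensusSet,
    consensus_b: ConsensusSet,
    mark: Optional[str] = None,
    min_score_ratio: Optional[float] = None,
    replicates_a: Optional[Sequence[PeakSet]] = None,
    replicates_b: Optional[Sequence[PeakSet]] = None,
) -> DifferentialRegionSet:
    """Condition-unique consensus regions (zero overlap against the other).

    When ``min_score_ratio`` is given along with the raw replicate sets,
    regions shared by both conditions are additionally screened by the ratio
    of mean replicate scores and reported separately (they never enter the
    unique sets, which stay strictly non-overlapping with the other
    condition).
    """
    a_hit = overlaps_any(consensus_a.peaks, consensus_b.peaks)
    b_hit = overlaps_any(consensus_b.peaks, consensus_a.peaks)
    a_unique = PeakSet([iv for iv, h in zip(consensus_a.peaks, a_hit) if not h])
    b_unique = PeakSet([iv for iv, h in zip(consensus_b.peaks, b_hit) if not h])

    a_enriched: List[GenomicInterval] = []
    b_enriched: List[GenomicInterval] = []
    if min_score_ratio is not None and replicates_a is not None and replicates_b is not None:
        sa = _mean_scores(consensus_a, replicates_a)
        sb_set = consensus_b.peaks
        sb = _mean_scores(consensus_b, replicates_b)
        # shared regions of A scored against the best-overlapping B score
        from .intervals import intersect_sets

        b_pos = {iv: i for i, iv in enumerate(sb_set)}
        best_b: dict = {}
        for a_region, b_region in intersect_sets(consensus_a.peaks, sb_set):
            sc = sb[b_pos[b_region]]
            if not np.isnan(sc):
                best_b[a_region] = max(best_b.get(a_region, 0.0), sc)
        for i, iv in enumerate(consensus_a.peaks):
            if a_hit[i] and iv in best_b and not np.isnan(sa[i]) and best_b[iv] > 0:
                if sa[i] / best_b[iv] > min_score_ratio:
                    a_enriched.append(iv)
        best_a: dict = {}
        a_pos = {iv: i for i, iv in enumerate(consensus_a.peaks)}
        for b_region, a_region in intersect_sets(sb_set, consensus_a.peaks):
            sc = sa[a_pos[a_region]]
            if not np.isnan(sc):
                best_a[b_region] = max(best_a.get(b_region, 0.0), sc)
        for i, iv in enumerate(sb_set):
            if b_hit[i] and iv in best_a and not np.isnan(sb[i]) and best_a[iv] > 0:
                if sb[i] / best_a[iv] > min_score_ratio:
                    b_enriched.append(iv)

    return DifferentialRegionSet(
        a_unique=a_unique,
        b_unique=b_unique,
        a_score_enriched=PeakSet(a_enriched),
        b_score_enriched=PeakSet(b_enriched),
        mark=mark,
    )
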