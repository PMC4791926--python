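"""Genomic-feature annotation of peaks.

Feature windows follow the conventions used for capture-based methylome
peak annotation against RefSeq-style gene models:

* promoter: 2.5 kb upstream to 500 bp downstream of the TSS (strand-aware);
* genic: from 500 bp downstream of the TSS to the transcript end;
* exon / intron: the transcript's exon blocks and the gaps between them;
* intergenic: peak midpoint more than 100 kb from every TSS;
* CGI: overlap with a CpG-island track; ``cgi_in_promoter`` additionally
  requires the CGI to overlap a promoter window and the peak to overlap
  that promoter window too;
* dhs_proximal: within 5 kb of a DNase I hypersensitive site.

A peak may carry several labels at once (features overlap), so per-feature
proportions need not sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    TSSIndex,
    merge_intervals,
    overlaps_any,
)

#: every label the classifier can emit
FEATURES: Tuple[str, ...] = (
    "promoter",
    "genic",
    "exon",
    "intron",
    "intergenic",
    "cgi",
    "cgi_in_promoter",
    "dhs_proximal",
)

#: the seven features used for cross-cell-line dynamics rows (Bonferroni m=7)
DYNAMICS_FEATURES: Tuple[str, ...] = (
    "intergenic",
    "genic",
    "exon",
    "intron",
    "promoter",
    "cgi",
    "dhs_proximal",
)


@dataclass(frozen=True)
class FeatureParams:
    """Window extents, in bp."""

    promoter_upstream: int = 2500
    promoter_downstream: int = 500
    intergenic_distance: int = 100_000
    dhs_radius: int = 5000

    def __post_init__(self) -> None:
        for name in ("promoter_upstream", "promoter_downstream",
                     "intergenic_distance", "dhs_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def _clip_window(chrom: str, start: int, end: int) -> Optional[GenomicInterval]:
    if start < 0:
        warnings.warn(f"window on {chrom} clipped at 0", stacklevel=3)
        start = 0
    if end <= start:
        return None
    return GenomicInterval(chrom, start, end)


def promoter_window(gene: GeneModel, params: FeatureParams) -> Optional[GenomicInterval]:
    """Strand-aware promoter window [TSS-up, TSS+down) (mirrored on -)."""
    tss = gene.tss
    if gene.strand == "+":
        return _clip_window(gene.chrom, tss - params.promoter_upstream,
                            tss + params.promoter_downstream)
    return _clip_window(gene.chrom, tss - params.promoter_downstream,
                        tss + params.promoter_upstream)


def genic_window(gene: GeneModel, params: FeatureParams) -> Optional[GenomicInterval]:
    """Transcript body beyond the promoter's downstream extent."""
    if gene.strand == "+":
        return _clip_window(gene.chrom, gene.tss + params.promoter_downstream,
                            gene.interval.end)
    return _clip_window(gene.chrom, gene.interval.start,
                        gene.tss - params.promoter_downstream)


class FeatureIndex:
    """Prebuilt per-feature window lookup for fast peak classification."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        cgis: Optional[PeakSet] = None,
        dhs: Optional[PeakSet] = None,
        params: FeatureParams = FeatureParams(),
    ):
        self.genes = list(genes)
        self.params = params
        self.tss_index = TSSIndex(self.genes)
        cgis = cgis if cgis is not None else PeakSet([])
        dhs = dhs if dhs is not None else PeakSet([])

        promoters = [w for g in self.genes if (w := promoter_window(g, params))]
        genic = [w for g in self.genes if (w := genic_window(g, params))]
        exons = [e for g in self.genes for e in g.exons]
        introns = [i for g in self.genes for i in g.introns]
        dhs_prox = [
            GenomicInterval(d.chrom, max(0, d.start - params.dhs_radius),
                            d.end + params.dhs_radius)
            for d in dhs
        ]
        promoter_set = merge_intervals(promoters)
        cgi_set = PeakSet(list(cgis))
        cgi_in_prom = [
            c for c, keep in zip(cgi_set, overlaps_any(cgi_set, promoter_set))
            if keep
        ]
        self.windows: Dict[str, PeakSet] = {
            "promoter": promoter_set,
            "genic": merge_intervals(genic),
            "exon": merge_intervals(exons),
            "intron": merge_intervals(introns),
            "cgi": merge_intervals(list(cgis)),
            "cgi_in_promoter": merge_intervals(cgi_in_prom),
            "dhs_proximal": merge_intervals(dhs_prox),
        }
        self._warned_chroms: set = set()

    def classify_matrix(self, peaks: PeakSet) -> np.ndarray:
        """Boolean matrix (n_peaks x len(FEATURES)) of label membership."""
        n = len(peaks)
        cols: Dict[str, np.ndarray] = {}
        for label, wset in self.windows.items():
            cols[label] = overlaps_any(peaks, wset)
        # genic holds wherever the genic window, an exon or an intron is hit
        cols["genic"] = cols["genic"] | cols["exon"] | cols["intron"]
        # cgi_in_promoter additionally requires the peak to touch a promoter
        cols["cgi_in_promoter"] = cols["cgi_in_promoter"] & cols["promoter"]
        # intergenic: midpoint farther than the threshold from every TSS,
        # never alongside promoter/genic
        _, dists = _nearest_distances(peaks, self.tss_index)
        far = np.abs(dists) > self.params.intergenic_distance
        no_genes = dists == np.int64(2) ** 62
        if no_genes.any():
            missing = {peaks[i].chrom for i in np.nonzero(no_genes)[0]}
            new = missing - self._warned_chroms
            if new:
                warnings.warn(
                    f"peaks on chromosome(s) {sorted(new)} have no annotated genes; "
                    "labelled intergenic", stacklevel=2)
                self._warned_chroms |= new
        cols["intergenic"] = (far | no_genes) & ~cols["promoter"] & ~cols["genic"]
        return np.column_stack([cols[f] for f in FEATURES])

    def classify(self, peak: GenomicInterval) -> FrozenSet[str]:
        row = self.classify_matrix(PeakSet([peak]))[0]
        return frozenset(f for f, hit in zip(FEATURES, row) if hit)


def _nearest_distances(peaks: PeakSet, index: TSSIndex):
    from .intervals import nearest_tss_bulk

    return nearest_tss_bulk(peaks, index)


def classify_peak(peak: GenomicInterval, index: FeatureIndex) -> FrozenSet[str]:
    """Feature label set for a single peak (pure function of its inputs)."""
    return index.classify(peak)


def feature_distribution(
    peaks: PeakSet,
    index: FeatureIndex,
    features: Sequence[str] = FEATURES,
) -> pd.DataFrame:
    """Per-feature peak counts and proportions (denominator = total peaks).

    A peak may count toward several features, so proportions need not sum
    to 1.  An empty peak set yields all-zero counts and proportions.
    """
    n = len(peaks)
    if n == 0:
        counts = np.zeros(len(features), dtype=int)
        props = np.zeros(len(features))
    else:
        matrix = index.classify_matrix(peaks)
        col = {f: i for i, f in enumerate(FEATURES)}
        counts = np.array([int(matrix[:, col[f]].sum()) for f in features])
        props = counts / n
    return pd.DataFrame(
        {"count": counts, "proportion": props}, index=pd.Index(features, name="feature")
    )
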