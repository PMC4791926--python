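"""Genomic interval primitives and the overlap algebra the pipeline builds on.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.  Two
intervals that share only a boundary coordinate therefore do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` with optional score/name."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.score is not None and self.score < 0:
            raise ValueError(f"negative score: {self.score}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return min(self.end, other.end) - max(self.start, other.start)

    def overlaps(self, other: "GenomicInterval", min_overlap_bp: int = 1) -> bool:
        return self.overlap_length(other) >= min_overlap_bp

    def intersection(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        """The shared span of two overlapping intervals, or None."""
        if self.overlap_length(other) <= 0:
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def sort_key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A stranded transcript with an ordered, disjoint exon structure."""

    interval: GenomicInterval
    gene_name: str
    exons: Tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_name}: strand must be + or -")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_name}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(
                    f"gene {self.gene_name}: exon {ex.start}-{ex.end} outside "
                    f"transcript span {self.interval.start}-{self.interval.end}"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_name}: exons unsorted/overlapping")
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start site: start for + strand, end for - strand."""
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def introns(self) -> Tuple[GenomicInterval, ...]:
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start > left.end:
                out.append(GenomicInterval(self.chrom, left.end, right.start))
        return tuple(out)


class PeakSet:
    """A sorted collection of GenomicIntervals with a label.

    The label is free-form; the pipeline uses ``(mark, cell_line, replicate)``
    tuples for sequencing peak sets and plain strings for annotation tracks.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label=None):
        self.intervals: List[GenomicInterval] = sorted(
            intervals, key=GenomicInterval.sort_key
        )
        self.label = label
        self._by_chrom: Optional[Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet(label={self.label!r}, n={len(self)})"

    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, index-into-self) arrays, start-sorted."""
        if self._by_chrom is None:
            table: Dict[str, List[List[int]]] = {}
            for i, iv in enumerate(self.intervals):
                table.setdefault(iv.chrom, [[], [], []])
                table[iv.chrom][0].append(iv.start)
                table[iv.chrom][1].append(iv.end)
                table[iv.chrom][2].append(i)
            self._by_chrom = {
                c: (
                    np.asarray(v[0], dtype=np.int64),
                    np.asarray(v[1], dtype=np.int64),
                    np.asarray(v[2], dtype=np.int64),
                )
                for c, v in table.items()
            }
        return self._by_chrom

    def total_bp(self) -> int:
        """Total covered basepairs after merging."""
        return sum(iv.width for iv in merge_intervals(self))


def merge_intervals(peaks: Iterable[GenomicInterval], label=None) -> PeakSet:
    """Merge overlapping or book-ended intervals; covered bp is preserved."""
    ivs = sorted(peaks, key=GenomicInterval.sort_key)
    merged: List[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return PeakSet(merged, label=label)


def intersect_sets(
    a: PeakSet, b: PeakSet, min_overlap_bp: int = 1
) -> List[Tuple[GenomicInterval, GenomicInterval]]:
    """Every pair (x in a, y in b) with overlap length >= min_overlap_bp.

    Symmetric: swapping the arguments yields the swapped pair list.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    pairs: List[Tuple[GenomicInterval, GenomicInterval]] = []
    b_chrom = b.by_chrom()
    for chrom, (a_starts, a_ends, a_idx) in a.by_chrom().items():
        if chrom not in b_chrom:
            continue
        b_starts, b_ends, b_idx = b_chrom[chrom]
        # candidates: b.start <= a.end - min_overlap; filter on overlap length
        hi = np.searchsorted(b_starts, a_ends - min_overlap_bp, side="right")
        for k in range(len(a_starts)):
            if hi[k] == 0:
                continue
            s, e = a_starts[k], a_ends[k]
            bs = b_starts[: hi[k]]
            be = b_ends[: hi[k]]
            ov = np.minimum(e, be) - np.maximum(s, bs)
            for j in np.nonzero(ov >= min_overlap_bp)[0]:
                pairs.append((a.intervals[a_idx[k]], b.intervals[b_idx[j]]))
    pairs.sort(key=lambda p: (p[0].sort_key(), p[1].sort_key()))
    return pairs


def overlaps_any(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> np.ndarray:
    """Boolean array over ``a.intervals``: does interval i overlap anything in b?

    Uses a prefix-max of ends over the start-sorted b intervals, so each query
    is O(log n) even when b is not merged.
    """
    out = np.zeros(len(a), dtype=bool)
    b_chrom = b.by_chrom()
    for chrom, (a_starts, a_ends, a_idx) in a.by_chrom().items():
        if chrom not in b_chrom:
            continue
        b_starts, b_ends, _ = b_chrom[chrom]
        prefix_max_end = np.maximum.accumulate(b_ends)
        hi = np.searchsorted(b_starts, a_ends - min_overlap_bp, side="right")
        ok = hi > 0
        # longest reach among candidate b's must extend min_overlap past a.start
        reach = np.where(ok, prefix_max_end[np.maximum(hi - 1, 0)], 0)
        out[a_idx] = ok & (reach >= a_starts + min_overlap_bp)
    return out


def _dedup_longest(genes: Sequence[GeneModel]) -> List[GeneModel]:
    """Collapse duplicate gene names, keeping the longest transcript."""
    best: Dict[str, GeneModel] = {}
    for g in genes:
        cur = best.get(g.gene_name)
        if cur is None or g.interval.width > cur.interval.width:
            best[g.gene_name] = g
    return sorted(best.values(), key=lambda g: g.interval.sort_key())


class TSSIndex:
    """Per-chromosome sorted TSS positions for fast nearest-gene queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        table: Dict[str, List[Tuple[int, str]]] = {}
        for g in self.genes:
            table.setdefault(g.chrom, []).append((g.tss, g.gene_name))
        self._chrom: Dict[str, Tuple[np.ndarray, List[str]]] = {}
        for chrom, items in table.items():
            items.sort()
            pos = np.asarray([p for p, _ in items], dtype=np.int64)
            # per position keep the lexicographically smallest name for ties
            names: List[str] = []
            name_at: Dict[int, str] = {}
            for p, n in items:
                if p not in name_at or n < name_at[p]:
                    name_at[p] = n
            names = [name_at[int(p)] for p in pos]
            self._chrom[chrom] = (pos, names)

    def nearest(self, chrom: str, point: int) -> Optional[Tuple[str, int]]:
        """Nearest TSS to ``point``: (gene_name, signed distance point - tss).

        Ties (equidistant TSSs, or several genes sharing one TSS) resolve to
        the lexicographically smallest gene name; among equal distances and
        names the left (upstream in genome coordinates) TSS wins.
        """
        if chrom not in self._chrom:
            return None
        pos, names = self._chrom[chrom]
        i = int(np.searchsorted(pos, point))
        cands = []
        if i > 0:
            cands.append((abs(point - int(pos[i - 1])), names[i - 1], int(pos[i - 1])))
        if i < len(pos):
            cands.append((abs(point - int(pos[i])), names[i], int(pos[i])))
        d, name, tss = min(cands)
        return name, point - tss

    def nearest_bulk(self, chrom: str, points: np.ndarray):
        """Vectorised nearest-TSS lookup for many points on one chromosome.

        Returns (names list, signed distances array) or None if the
        chromosome has no genes.
        """
        if chrom not in self._chrom:
            return None
        pos, names = self._chrom[chrom]
        points = np.asarray(points, dtype=np.int64)
        i = np.searchsorted(pos, points)
        left = np.maximum(i - 1, 0)
        right = np.minimum(i, len(pos) - 1)
        d_left = np.abs(points - pos[left])
        d_right = np.abs(points - pos[right])
        # prefer left on exact distance ties unless the right-hand name sorts
        # strictly smaller (deterministic lexicographic rule)
        use_left = (d_left < d_right) | (
            (d_left == d_right)
            & np.array([names[l] <= names[r] for l, r in zip(left, right)])
        )
        idx = np.where(use_left, left, right)
        out_names = [names[j] for j in idx]
        dist = points - pos[idx]
        return out_names, dist


def nearest_tss(
    peak: GenomicInterval, genes: Sequence[GeneModel] | TSSIndex
) -> Optional[Tuple[str, int]]:
    """Nearest gene to the peak midpoint by TSS distance.

    Returns ``(gene_name, signed_distance)`` with signed distance measured as
    ``midpoint - TSS`` in genome coordinates, or None when the peak's
    chromosome carries no genes.
    """
    index = genes if isinstance(genes, TSSIndex) else TSSIndex(genes)
    return index.nearest(peak.chrom, peak.midpoint)


def nearest_tss_bulk(peaks: PeakSet, index: TSSIndex):
    """Nearest-TSS gene names and signed distances for every peak.

    Peaks on chromosomes without genes get ``None`` / distance 2**62.
    """
    names: List[Optional[str]] = [None] * len(peaks)
    dists = np.full(len(peaks), np.int64(2) ** 62, dtype=np.int64)
    for chrom, (starts, ends, idx) in peaks.by_chrom().items():
        mids = (starts + ends) // 2
        res = index.nearest_bulk(chrom, mids)
        if res is None:
            continue
        chrom_names, chrom_d = res
        for k, i in enumerate(idx):
            names[i] = chrom_names[k]
        dists[idx] = chrom_d
    return names, dists
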