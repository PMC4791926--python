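import numpy as np
import pytest

from hydromark.annotation import FeatureIndex, FeatureParams
from hydromark.intervals import GeneModel, GenomicInterval, PeakSet


def random_peakset(rng, n, chroms=("chr1", "chr2"), coord_max=5000,
                   max_width=200, label=None):
    """A random PeakSet for oracle comparisons (small coordinate space so
    overlaps are frequent)."""
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, coord_max))
        width = int(rng.integers(1, max_width))
        ivs.append(GenomicInterval(chrom, start, start + width))
    return PeakSet(ivs, label=label)


def brute_force_pairs(a, b, min_overlap=1):
    """All-vs-all O(n^2) overlap oracle."""
    pairs = []
    for x in a:
        for y in b:
            if x.chrom == y.chrom and min(x.end, y.end) - max(x.start, y.start) >= min_overlap:
                pairs.append((x, y))
    pairs.sort(key=lambda p: (p[0].sort_key(), p[1].sort_key()))
    return pairs


def coverage_oracle(peaks, coord_max=10_000):
    """Per-base occupancy oracle: total covered bp per chromosome."""
    covered = {}
    for iv in peaks:
        occ = covered.setdefault(iv.chrom, np.zeros(coord_max, dtype=bool))
        occ[iv.start:iv.end] = True
    return {c: int(occ.sum()) for c, occ in covered.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20160315)


def _gene(chrom, start, end, strand, name, exon_bounds=None):
    exons = tuple(
        GenomicInterval(chrom, s, e) for s, e in (exon_bounds or [(start, end)])
    )
    return GeneModel(GenomicInterval(chrom, start, end, strand=strand),
                     gene_name=name, exons=exons)


@pytest.fixture
def ten_gene_index():
    """A hand-built 10-gene fixture (both strands) with CGI and DHS tracks.

    Window arithmetic for each gene is recomputed by hand in the tests that
    use this fixture.
    """
    genes = [
        _gene("chr1", 10_000, 20_000, "+", "GA",
              exon_bounds=[(10_000, 12_000), (15_000, 20_000)]),
        _gene("chr1", 50_000, 55_000, "-", "GB",
              exon_bounds=[(50_000, 51_000), (53_000, 55_000)]),
        _gene("chr1", 300_000, 320_000, "+", "GC"),
        _gene("chr1", 600_000, 640_000, "-", "GD",
              exon_bounds=[(600_000, 610_000), (620_000, 640_000)]),
        _gene("chr1", 1_000_000, 1_005_000, "+", "GE"),
        _gene("chr2", 8_000, 30_000, "+", "GF",
              exon_bounds=[(8_000, 9_000), (29_000, 30_000)]),
        _gene("chr2", 100_000, 140_000, "-", "GG"),
        _gene("chr2", 500_000, 505_000, "+", "GH"),
        _gene("chr2", 505_500, 520_000, "-", "GI"),
        _gene("chr2", 2_000_000, 2_010_000, "+", "GJ"),
    ]
    cgis = PeakSet([
        GenomicInterval("chr1", 9_000, 10_500),    # spans GA promoter + TSS
        GenomicInterval("chr1", 400_000, 401_000),  # isolated CGI
        GenomicInterval("chr2", 99_500, 100_200),   # not in GG promoter (wrong side)
    ], label="CGI")
    dhs = PeakSet([
        GenomicInterval("chr1", 30_000, 30_200),
        GenomicInterval("chr2", 140_500, 140_700),
    ], label="DHS")
    return FeatureIndex(genes, cgis, dhs, FeatureParams()), genes
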