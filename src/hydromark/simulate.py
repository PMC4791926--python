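"""Synthetic genome, mark peak sets, and expression tables.

The generator emulates the statistical structure of a paired
normal-vs-cancer cell-line methylome/hydroxymethylome experiment:

* a toy genome of gene clusters separated by intergenic deserts wider than
  the 100-kb intergenic threshold, with CGIs concentrated at TSSs, DHS
  sites near regulatory regions, and CpG positions denser inside CGIs;
* per (mark, condition) peak sets placed with configurable feature bias:
  three jittered replicates per 5mC set (capture-seq style), one replicate
  per 5hmC set; the cancer condition loses 5hmC globally but gains
  intergenic placement weight;
* expression tables whose values respond to mark presence through per-tier
  odds multipliers (realised as a log2(multiplier) shift of the latent
  log-expression in units of its SD): genic 5hmC pushes expression up,
  intergenic 5hmC pushes it down, mirroring the association structure the
  pipeline is built to detect.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import FeatureIndex, FeatureParams
from .intervals import GeneModel, GenomicInterval, PeakSet, merge_intervals
from .io import GeneSetCollection

MARKS = ("5mC", "5hmC")
CONDITIONS = ("normal", "cancer")

#: peak-placement categories the bias weights range over
PLACEMENT_FEATURES = ("promoter", "genic", "cgi", "dhs", "intergenic")


def _default_bias_weights() -> Dict[Tuple[str, str], Dict[str, float]]:
    return {
        ("5mC", "normal"): {"promoter": 0.12, "genic": 0.35, "cgi": 0.13,
                            "dhs": 0.10, "intergenic": 0.30},
        ("5mC", "cancer"): {"promoter": 0.08, "genic": 0.30, "cgi": 0.24,
                            "dhs": 0.16, "intergenic": 0.22},
        ("5hmC", "normal"): {"promoter": 0.12, "genic": 0.40, "cgi": 0.12,
                             "dhs": 0.12, "intergenic": 0.24},
        # global 5hmC loss with doubled intergenic placement weight in cancer
        ("5hmC", "cancer"): {"promoter": 0.06, "genic": 0.28, "cgi": 0.08,
                             "dhs": 0.10, "intergenic": 0.48},
    }


def _default_peak_counts() -> Dict[Tuple[str, str], int]:
    return {
        ("5mC", "normal"): 2000,
        ("5mC", "cancer"): 2200,
        ("5hmC", "normal"): 2000,
        # cancer 5hmC count = normal x hmc_loss_factor (applied at build time)
        ("5hmC", "cancer"): -1,
    }


def _default_expression_effects() -> Dict[Tuple[str, str], float]:
    # (mark, feature) -> per-tier odds multiplier; 1.0 means no effect
    return {
        ("5hmC", "genic"): 2.0,
        ("5hmC", "dhs_proximal"): 1.5,
        ("5hmC", "intergenic"): 0.5,
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 300
    gene_length_range: Tuple[int, int] = (2_000, 20_000)
    exon_count_range: Tuple[int, int] = (2, 8)
    n_deserts_per_chrom: int = 8           # intergenic deserts between clusters
    desert_width_range: Tuple[int, int] = (250_000, 400_000)
    n_cgis: int = 200
    cgi_width_range: Tuple[int, int] = (300, 2_000)
    cgi_tss_fraction: float = 0.6          # CGIs placed at a TSS
    n_dhs: int = 150
    dhs_width_range: Tuple[int, int] = (150, 500)
    dhs_tss_fraction: float = 0.5
    n_cpgs: int = 20_000
    cpg_cgi_fraction: float = 0.4          # CpG positions landing inside CGIs
    peak_width_range: Tuple[int, int] = (300, 1_500)
    peak_counts: Dict[Tuple[str, str], int] = field(default_factory=_default_peak_counts)
    hmc_loss_factor: float = 0.5           # cancer 5hmC total vs. normal
    bias_weights: Dict[Tuple[str, str], Dict[str, float]] = field(
        default_factory=_default_bias_weights)
    n_replicates_5mc: int = 3
    n_replicates_5hmc: int = 1
    replicate_jitter_sd: float = 30.0      # bp positional jitter per replicate
    replicate_dropout: float = 0.10
    expression_effects: Dict[Tuple[str, str], float] = field(
        default_factory=_default_expression_effects)
    expression_mean: float = 8.0           # latent log2-expression baseline
    expression_sd: float = 2.0
    expression_noise_sd: float = 0.25      # replicate measurement noise
    n_expression_replicates: int = 3
    n_gene_sets: int = 30
    gene_set_size_range: Tuple[int, int] = (10, 40)
    feature_params: FeatureParams = field(default_factory=FeatureParams)

    def null(self) -> "SyntheticConfig":
        """A copy with every planted effect switched off."""
        flat = {k: 1.0 for k in self.expression_effects}
        weights = {key: dict(self.bias_weights[("5mC", "normal")])
                   for key in self.bias_weights}
        return replace(self, expression_effects=flat, bias_weights=weights,
                       hmc_loss_factor=1.0)


@dataclass
class SyntheticGenome:
    genes: List[GeneModel]
    cgis: PeakSet
    dhs: PeakSet
    cpgs: PeakSet
    chrom_lengths: Dict[str, int]
    intergenic_cores: PeakSet  # zones > intergenic threshold from every TSS


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: SyntheticGenome
    index: FeatureIndex
    #: (mark, condition) -> list of replicate PeakSets
    marks: Dict[Tuple[str, str], List[PeakSet]]
    #: (mark, condition) -> the pre-jitter base PeakSet
    base_marks: Dict[Tuple[str, str], PeakSet]
    #: condition -> replicate expression table (gene, rep1..repR)
    expression: Dict[str, pd.DataFrame]
    gene_sets: GeneSetCollection


def _place_genes_on_chrom(
    rng: np.random.Generator, cfg: SyntheticConfig, chrom: str, n_genes: int
) -> Tuple[List[GeneModel], List[GenomicInterval]]:
    """Lay out gene clusters separated by wide deserts; returns genes and
    the desert intervals."""
    L = cfg.chrom_length
    desert_widths = rng.integers(cfg.desert_width_range[0],
                                 cfg.desert_width_range[1] + 1,
                                 size=cfg.n_deserts_per_chrom)
    total_desert = int(desert_widths.sum())
    gene_lengths = rng.integers(cfg.gene_length_range[0],
                                cfg.gene_length_range[1] + 1, size=n_genes)
    total_gene = int(gene_lengths.sum())
    margin = 5_000  # keep promoters on-chromosome
    free = L - total_desert - total_gene - 2 * margin
    if free <= n_genes + cfg.n_deserts_per_chrom:
        raise ValueError("chromosome too small for requested genes and deserts")

    # order: alternate gene blocks and deserts; distribute free space as
    # random gaps between consecutive placed elements
    n_clusters = cfg.n_deserts_per_chrom + 1
    cluster_of_gene = np.sort(rng.integers(0, n_clusters, size=n_genes))
    n_slots = n_genes + cfg.n_deserts_per_chrom + 1
    gaps = rng.multinomial(free, np.full(n_slots, 1.0 / n_slots))

    genes: List[GeneModel] = []
    deserts: List[GenomicInterval] = []
    pos = margin
    slot = 0
    gi = 0
    for cluster in range(n_clusters):
        in_cluster = int((cluster_of_gene == cluster).sum())
        for _ in range(in_cluster):
            pos += int(gaps[slot]); slot += 1
            length = int(gene_lengths[gi])
            start, end = pos, pos + length
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(cfg.exon_count_range[0],
                                    cfg.exon_count_range[1] + 1))
            n_ex = min(n_ex, max(1, length // 400))
            cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex - 2,
                                      replace=False)) if n_ex > 1 else np.array([], int)
            bounds = np.concatenate([[0], cuts, [length]])
            exons = tuple(
                GenomicInterval(chrom, start + int(bounds[2 * j]),
                                start + int(bounds[2 * j + 1]))
                for j in range(n_ex)
            )
            genes.append(GeneModel(
                GenomicInterval(chrom, start, end, strand=strand),
                gene_name=f"{chrom}_G{gi:04d}", exons=exons))
            pos = end
            gi += 1
        if cluster < cfg.n_deserts_per_chrom:
            pos += int(gaps[slot]); slot += 1
            w = int(desert_widths[cluster])
            deserts.append(GenomicInterval(chrom, pos, pos + w))
            pos += w
    return genes, deserts


def generate_genome(cfg: SyntheticConfig,
                    rng: Optional[np.random.Generator] = None) -> SyntheticGenome:
    """Build the toy genome: genes, CGI/DHS/CpG tracks, intergenic cores."""
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    chrom_lengths = {f"chr{i+1}": cfg.chrom_length for i in range(cfg.n_chromosomes)}
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1
    genes: List[GeneModel] = []
    deserts: List[GenomicInterval] = []
    for i, chrom in enumerate(chrom_lengths):
        g, d = _place_genes_on_chrom(rng, cfg, chrom, int(per_chrom[i]))
        genes.extend(g)
        deserts.extend(d)

    tss_list = [(g.chrom, g.tss) for g in genes]

    def _near_tss_intervals(n: int, width_range, frac_tss: float):
        out = []
        for _ in range(n):
            w = int(rng.integers(width_range[0], width_range[1] + 1))
            if rng.random() < frac_tss and tss_list:
                chrom, tss = tss_list[int(rng.integers(len(tss_list)))]
                center = tss + int(rng.integers(-500, 501))
            else:
                chrom = f"chr{int(rng.integers(cfg.n_chromosomes)) + 1}"
                center = int(rng.integers(w, cfg.chrom_length - w))
            start = max(0, center - w // 2)
            out.append(GenomicInterval(chrom, start, start + w))
        return out

    cgis = merge_intervals(
        _near_tss_intervals(cfg.n_cgis, cfg.cgi_width_range, cfg.cgi_tss_fraction),
        label="CGI") if cfg.n_cgis > 0 else PeakSet([], label="CGI")
    dhs = merge_intervals(
        _near_tss_intervals(cfg.n_dhs, cfg.dhs_width_range, cfg.dhs_tss_fraction),
        label="DHS") if cfg.n_dhs > 0 else PeakSet([], label="DHS")

    # CpG positions: a configurable fraction inside CGIs, the rest uniform
    cpg_positions: List[GenomicInterval] = []
    n_in_cgi = int(round(cfg.n_cpgs * cfg.cpg_cgi_fraction)) if len(cgis) else 0
    if n_in_cgi:
        widths = np.array([iv.width for iv in cgis], dtype=float)
        choice = rng.choice(len(cgis), size=n_in_cgi, p=widths / widths.sum())
        for ci in choice:
            iv = cgis[int(ci)]
            p = int(rng.integers(iv.start, iv.end))
            cpg_positions.append(GenomicInterval(iv.chrom, p, p + 2))
    for _ in range(cfg.n_cpgs - n_in_cgi):
        chrom = f"chr{int(rng.integers(cfg.n_chromosomes)) + 1}"
        p = int(rng.integers(0, cfg.chrom_length - 2))
        cpg_positions.append(GenomicInterval(chrom, p, p + 2))
    cpgs = PeakSet(cpg_positions, label="CpG")

    # intergenic cores: desert interiors farther than the threshold from the
    # flanking TSSs (margin also covers peak half-width placement slack)
    thresh = cfg.feature_params.intergenic_distance
    pad = thresh + cfg.peak_width_range[1]
    cores = []
    for d in deserts:
        if d.width > 2 * pad + 1000:
            cores.append(GenomicInterval(d.chrom, d.start + pad, d.end - pad))
    return SyntheticGenome(
        genes=genes, cgis=cgis, dhs=dhs, cpgs=cpgs,
        chrom_lengths=chrom_lengths,
        intergenic_cores=PeakSet(cores, label="intergenic_core"),
    )


def _sample_peaks_in(rng: np.random.Generator, windows: Sequence[GenomicInterval],
                     n: int, width_range: Tuple[int, int],
                     chrom_lengths: Dict[str, int]) -> List[GenomicInterval]:
    """n peaks whose midpoints fall uniformly in the given windows
    (windows chosen width-proportionally)."""
    if not windows:
        return []
    widths = np.array([w.width for w in windows], dtype=float)
    probs = widths / widths.sum()
    picks = rng.choice(len(windows), size=n, p=probs)
    out = []
    for wi in picks:
        w = windows[int(wi)]
        pw = int(rng.integers(width_range[0], width_range[1] + 1))
        mid = int(rng.integers(w.start, w.end))
        start = max(0, mid - pw // 2)
        end = min(chrom_lengths[w.chrom], start + pw)
        out.append(GenomicInterval(w.chrom, start, end,
                                   score=float(np.round(rng.uniform(10, 200), 3))))
    return out


def generate_marks(
    cfg: SyntheticConfig,
    genome: SyntheticGenome,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[Tuple[str, str], List[PeakSet]], Dict[Tuple[str, str], PeakSet]]:
    """Per-(mark, condition) replicate peak sets plus the pre-jitter bases."""
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    params = cfg.feature_params

    placement: Dict[str, List[GenomicInterval]] = {
        "promoter": [], "genic": [], "cgi": list(genome.cgis),
        "dhs": list(genome.dhs), "intergenic": list(genome.intergenic_cores),
    }
    from .annotation import genic_window, promoter_window

    for g in genome.genes:
        pw = promoter_window(g, params)
        gw = genic_window(g, params)
        if pw:
            placement["promoter"].append(pw)
        if gw:
            placement["genic"].append(gw)

    replicate_counts = {"5mC": cfg.n_replicates_5mc, "5hmC": cfg.n_replicates_5hmc}
    marks: Dict[Tuple[str, str], List[PeakSet]] = {}
    bases: Dict[Tuple[str, str], PeakSet] = {}
    for mark in MARKS:
        for condition in CONDITIONS:
            key = (mark, condition)
            n_peaks = cfg.peak_counts[key]
            if n_peaks < 0:  # sentinel: cancer 5hmC scales off the normal count
                n_peaks = int(round(cfg.peak_counts[(mark, "normal")]
                                    * cfg.hmc_loss_factor))
            weights = cfg.bias_weights[key]
            wvec = np.array([max(0.0, weights.get(f, 0.0))
                             for f in PLACEMENT_FEATURES])
            if wvec.sum() <= 0:
                raise ValueError(f"bias weights for {key} are all zero")
            wvec = wvec / wvec.sum()
            counts = rng.multinomial(n_peaks, wvec)
            peaks: List[GenomicInterval] = []
            for f, n_f in zip(PLACEMENT_FEATURES, counts):
                peaks.extend(_sample_peaks_in(rng, placement[f], int(n_f),
                                              cfg.peak_width_range,
                                              genome.chrom_lengths))
            base = PeakSet(peaks, label=(mark, condition, "base"))
            bases[key] = base
            reps = []
            for r in range(replicate_counts[mark]):
                if cfg.replicate_jitter_sd == 0 and cfg.replicate_dropout == 0:
                    reps.append(PeakSet(list(base), label=(mark, condition, r + 1)))
                    continue
                keep = rng.random(len(base)) >= cfg.replicate_dropout
                shifts = np.round(rng.normal(0, cfg.replicate_jitter_sd,
                                             len(base))).astype(int)
                ivs = []
                for i, iv in enumerate(base):
                    if not keep[i]:
                        continue
                    s = max(0, iv.start + int(shifts[i]))
                    e = s + iv.width
                    ivs.append(GenomicInterval(iv.chrom, s, e, score=iv.score))
                reps.append(PeakSet(ivs, label=(mark, condition, r + 1)))
            marks[key] = reps
    return marks, bases


def generate_expression(
    cfg: SyntheticConfig,
    genome: SyntheticGenome,
    base_marks: Dict[Tuple[str, str], PeakSet],
    index: Optional[FeatureIndex] = None,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, pd.DataFrame]:
    """Condition-wise expression tables responding to mark placement.

    Each configured (mark, feature) odds multiplier m shifts the latent
    log-expression of genes carrying that mark in that feature by
    log2(m) * expression_sd; m = 1 leaves the null intact.  Replicate
    columns add independent Gaussian measurement noise.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    index = index or FeatureIndex(genome.genes, genome.cgis, genome.dhs,
                                  cfg.feature_params)
    from .intervals import nearest_tss_bulk
    from .annotation import FEATURES

    gene_names = [g.gene_name for g in genome.genes]
    gene_pos = {name: i for i, name in enumerate(gene_names)}
    col = {f: i for i, f in enumerate(FEATURES)}
    out: Dict[str, pd.DataFrame] = {}
    for condition in CONDITIONS:
        base = rng.normal(cfg.expression_mean, cfg.expression_sd, len(gene_names))
        for (mark, feature), mult in sorted(cfg.expression_effects.items()):
            if mult == 1.0:
                continue
            peaks = base_marks[(mark, condition)]
            names, _ = nearest_tss_bulk(peaks, index.tss_index)
            matrix = index.classify_matrix(peaks)
            marked = {names[i] for i in range(len(peaks))
                      if names[i] is not None and matrix[i, col[feature]]}
            shift = np.log2(mult) * cfg.expression_sd
            for g in marked:
                base[gene_pos[g]] += shift
        reps = {
            f"rep{r+1}": base + rng.normal(0, cfg.expression_noise_sd, len(base))
            for r in range(cfg.n_expression_replicates)
        }
        out[condition] = pd.DataFrame({"gene": gene_names, **reps})
    return out


def generate_gene_sets(
    cfg: SyntheticConfig,
    genome: SyntheticGenome,
    rng: Optional[np.random.Generator] = None,
) -> GeneSetCollection:
    """Random gene sets over the toy genome's gene universe."""
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    gene_names = [g.gene_name for g in genome.genes]
    sets = {}
    descriptions = {}
    for i in range(cfg.n_gene_sets):
        size = int(rng.integers(cfg.gene_set_size_range[0],
                                cfg.gene_set_size_range[1] + 1))
        size = min(size, len(gene_names))
        members = rng.choice(len(gene_names), size=size, replace=False)
        name = f"SET{i:03d}"
        sets[name] = frozenset(gene_names[j] for j in members)
        descriptions[name] = f"synthetic gene set {i}"
    return GeneSetCollection(sets, descriptions)


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """The full synthetic dataset, deterministic under cfg.seed."""
    genome = generate_genome(cfg)
    index = FeatureIndex(genome.genes, genome.cgis, genome.dhs, cfg.feature_params)
    marks, bases = generate_marks(cfg, genome)
    expression = generate_expression(cfg, genome, bases, index=index)
    gene_sets = generate_gene_sets(cfg, genome)
    return SyntheticDataset(config=cfg, genome=genome, index=index, marks=marks,
                            base_marks=bases, expression=expression,
                            gene_sets=gene_sets)


# ---------------------------------------------------------------------------
# Null-model simulators used for statistical calibration.  These draw from
# the exact null hypotheses of the corresponding tests: tier counts with
# marks independent of expression (multivariate hypergeometric given fixed
# margins), and per-feature in-feature counts binomially from a reference
# marginal proportion.

def simulate_null_tier_counts(
    rng: np.random.Generator, tier_totals: Sequence[int], n_marked: int
) -> np.ndarray:
    """Marked-gene counts per tier with marks independent of expression."""
    totals = np.asarray(tier_totals, dtype=np.int64)
    if not 0 <= n_marked <= totals.sum():
        raise ValueError("n_marked out of range")
    return rng.multivariate_hypergeometric(totals, n_marked)


def simulate_null_feature_counts(
    rng: np.random.Generator, total: int, proportions: Sequence[float],
    size: Optional[int] = None,
) -> np.ndarray:
    """In-feature counts drawn from the marginal: O_f ~ Binomial(T, p_f)."""
    p = np.asarray(proportions, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions outside [0, 1]")
    if size is None:
        return rng.binomial(total, p)
    return rng.binomial(total, p, size=(size, len(p)))
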