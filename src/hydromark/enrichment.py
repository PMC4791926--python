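"""Region-based gene-set enrichment and enrichment-map edges.

Regions are mapped to genes by nearest TSS; each gene set is tested by an
upper-tail hypergeometric test of foreground membership against a
user-supplied region-derived background, with Benjamini-Hochberg FDR across
sets.  Significant sets can be linked into an enrichment map by Jaccard
similarity of their enriched-gene lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import FeatureIndex
from .intervals import PeakSet, nearest_tss_bulk
from .io import GeneSetCollection


def regions_to_genes(regions: PeakSet, index: FeatureIndex) -> Set[str]:
    """Unique nearest-TSS genes of a region set."""
    names, _ = nearest_tss_bulk(regions, index.tss_index)
    return {n for n in names if n is not None}


def hypergeometric_enrichment(
    foreground_genes: Set[str],
    background_genes: Set[str],
    gene_sets: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    Draws n = |foreground| genes from N = |background|; a set with K
    background members yields p = P(X >= k) for the k observed foreground
    members.  Sets with no background members are skipped (flagged
    ``no_background``).  BH FDR is computed across the tested sets.
    """
    if not foreground_genes:
        raise ValueError("empty foreground gene list")
    bg = set(background_genes)
    fg = set(foreground_genes)
    if not fg <= bg:
        warnings.warn(
            f"{len(fg - bg)} foreground genes absent from background; "
            "background extended to include them", stacklevel=2)
        bg = bg | fg
    N, n = len(bg), len(fg)
    rows = []
    for name, members in gene_sets:
        K = len(members & bg)
        if K == 0:
            rows.append({"set": name, "k": 0, "n": n, "K": 0, "N": N,
                         "p": np.nan, "no_background": True, "genes": ""})
            continue
        hit_genes = sorted(members & fg)
        k = len(hit_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"set": name, "k": k, "n": n, "K": K, "N": N,
                     "p": min(p, 1.0), "no_background": False,
                     "genes": ",".join(hit_genes)})
    df = pd.DataFrame(rows)
    tested = ~df["no_background"]
    fdr = np.full(len(df), np.nan)
    if tested.any():
        fdr[tested.values] = stats.false_discovery_control(
            df.loc[tested, "p"].values, method="bh")
    df["fdr"] = fdr
    return df.sort_values(["p", "set"], na_position="last").reset_index(drop=True)


def region_enrichment(
    foreground_regions: PeakSet,
    background_regions: PeakSet,
    gene_sets: GeneSetCollection,
    index: FeatureIndex,
) -> pd.DataFrame:
    """Hypergeometric gene-set enrichment of region-associated genes.

    The background region list should contain the complete set of marked
    regions in both conditions (no significance threshold); foreground
    genes not covered by the background are united into it with a warning.
    """
    if len(foreground_regions) == 0:
        raise ValueError("empty foreground region set")
    fg = regions_to_genes(foreground_regions, index)
    bg = regions_to_genes(background_regions, index)
    return hypergeometric_enrichment(fg, bg, gene_sets)


def jaccard(a: Set[str], b: Set[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def similarity_edges(
    results: pd.DataFrame,
    jaccard_threshold: float = 0.25,
    p_max: float = 0.05,
    fdr_max: float = 0.1,
    edge_when: str = "at_least",
) -> pd.DataFrame:
    """Enrichment-map edges between significant sets.

    Nodes are sets passing the p and FDR thresholds.  ``edge_when`` selects
    the similarity direction: ``"at_least"`` (the conventional
    enrichment-map rule: edge when Jaccard >= threshold) or ``"below"``
    (edge when Jaccard < threshold).  Both are offered because published
    legends sometimes print the inverted inequality; the conventional
    reading is the default.
    """
    if edge_when not in ("at_least", "below"):
        raise ValueError("edge_when must be 'at_least' or 'below'")
    sig = results[(results["p"] < p_max) & (results["fdr"] < fdr_max)
                  & ~results["no_background"]]
    gene_lists = {
        row["set"]: set(row["genes"].split(",")) if row["genes"] else set()
        for _, row in sig.iterrows()
    }
    names = sorted(gene_lists)
    rows = []
    for i, s1 in enumerate(names):
        for s2 in names[i + 1:]:
            j = jaccard(gene_lists[s1], gene_lists[s2])
            keep = (j >= jaccard_threshold) if edge_when == "at_least" else (j < jaccard_threshold)
            if keep:
                rows.append({"set1": s1, "set2": s2, "jaccard": j})
    return pd.DataFrame(rows, columns=["set1", "set2", "jaccard"])
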