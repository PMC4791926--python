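"""End-to-end orchestration: annotation -> consensus -> expression
correlation -> fate dynamics -> co-incidence -> enrichment, with a
machine-readable run log.

The pipeline runs either from a synthetic dataset (seeded, fully
deterministic) or from files on disk declared in a RunConfig.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .annotation import DYNAMICS_FEATURES, FEATURES, FeatureIndex, FeatureParams, feature_distribution
from .consensus import consensus_peaks, differential_regions
from .dynamics import (
    CLASS_NAMES,
    classify_dynamics,
    coincidence_regions,
    compare_dynamic_classes,
    dynamics_table,
    random_background_expectation,
)
from .enrichment import region_enrichment, similarity_edges
from .expression import assign_peaks_to_tiers, association_table, tier_split
from .intervals import PeakSet, merge_intervals
from .io import (
    GeneSetCollection,
    read_bed,
    read_expression,
    read_gene_models,
    read_gmt,
    write_bed,
)
from .simulate import CONDITIONS, MARKS, SyntheticConfig, SyntheticDataset, generate_dataset

_FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Pipeline thresholds and (optionally) input file paths."""

    outdir: str = "hydromark_out"
    seed: int = 0
    simulate: bool = True
    feature_params: FeatureParams = field(default_factory=FeatureParams)
    n_tiers: int = 3
    alpha: float = 0.05
    bonferroni_m: int = len(DYNAMICS_FEATURES)
    consensus_k_5mc: int = 3
    consensus_k_5hmc: int = 1
    enrichment_p_max: float = 0.05
    enrichment_fdr_max: float = 0.1
    jaccard_threshold: float = 0.25
    jaccard_edge_when: str = "at_least"
    # file-based inputs (used when simulate is False)
    genes_path: Optional[str] = None
    cgi_path: Optional[str] = None
    dhs_path: Optional[str] = None
    cpg_path: Optional[str] = None
    gmt_path: Optional[str] = None
    #: (mark, condition) -> list of replicate BED paths
    peak_paths: Dict[Tuple[str, str], List[str]] = field(default_factory=dict)
    #: condition -> expression TSV path
    expression_paths: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class LoadedInputs:
    index: FeatureIndex
    marks: Dict[Tuple[str, str], List[PeakSet]]
    expression: Dict[str, pd.Series]
    gene_sets: Optional[GeneSetCollection]
    cpgs: Optional[PeakSet]


def _load_from_files(config: RunConfig) -> LoadedInputs:
    if config.genes_path is None:
        raise ValueError("genes_path is required when simulate is False")
    genes = read_gene_models(config.genes_path)
    cgis = read_bed(config.cgi_path, "CGI") if config.cgi_path else None
    dhs = read_bed(config.dhs_path, "DHS") if config.dhs_path else None
    index = FeatureIndex(genes, cgis, dhs, config.feature_params)
    marks: Dict[Tuple[str, str], List[PeakSet]] = {}
    for (mark, condition), paths in config.peak_paths.items():
        if not paths:
            raise ValueError(f"no replicate paths for ({mark}, {condition})")
        marks[(mark, condition)] = [
            read_bed(p, (mark, condition, i + 1)) for i, p in enumerate(paths)
        ]
    expression = {c: read_expression(p) for c, p in config.expression_paths.items()}
    gene_sets = read_gmt(config.gmt_path) if config.gmt_path else None
    cpgs = read_bed(config.cpg_path, "CpG") if config.cpg_path else None
    return LoadedInputs(index=index, marks=marks, expression=expression,
                        gene_sets=gene_sets, cpgs=cpgs)


def _inputs_from_dataset(ds: SyntheticDataset) -> LoadedInputs:
    expression = {}
    for condition, df in ds.expression.items():
        reps = [c for c in df.columns if c != "gene"]
        s = df[reps].mean(axis=1)
        s.index = df["gene"]
        expression[condition] = s
    return LoadedInputs(index=ds.index, marks=ds.marks, expression=expression,
                        gene_sets=ds.gene_sets, cpgs=ds.genome.cpgs)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT, index=index)


def run_pipeline(config: RunConfig,
                 dataset: Optional[SyntheticDataset] = None) -> Dict[str, object]:
    """Run every stage and write the report bundle into config.outdir.

    Returns a dict of in-memory stage results keyed by stage name.  Any
    stage failure raises with the stage name prefixed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}

    stage = "load"
    try:
        if dataset is None and config.simulate:
            dataset = generate_dataset(SyntheticConfig(seed=config.seed))
        inputs = _inputs_from_dataset(dataset) if dataset is not None \
            else _load_from_files(config)
        index = inputs.index

        required = [(m, c) for m in MARKS for c in CONDITIONS]
        missing = [k for k in required if k not in inputs.marks]
        if missing:
            raise ValueError(f"missing peak sets for {missing}")

        stage = "consensus"
        k_of = {"5mC": config.consensus_k_5mc, "5hmC": config.consensus_k_5hmc}
        consensus = {
            key: consensus_peaks(reps, k=min(k_of[key[0]], len(reps)), label=key)
            for key, reps in inputs.marks.items()
        }
        cons_rows = []
        for (mark, condition), cs in sorted(consensus.items()):
            write_bed(cs.peaks, outdir / f"consensus_{mark}_{condition}.bed")
            cons_rows.append({"mark": mark, "condition": condition,
                              "k": cs.min_support, "n_replicates": cs.n_replicates,
                              "n_regions": len(cs)})
        _write(pd.DataFrame(cons_rows), outdir / "consensus_summary.tsv", index=False)
        results["consensus"] = consensus

        stage = "differential"
        differential = {}
        diff_rows = []
        for mark in MARKS:
            d = differential_regions(consensus[(mark, "normal")],
                                     consensus[(mark, "cancer")], mark=mark)
            differential[mark] = d
            write_bed(d.a_unique, outdir / f"differential_{mark}_normal_unique.bed")
            write_bed(d.b_unique, outdir / f"differential_{mark}_cancer_unique.bed")
            diff_rows.append({"mark": mark, "normal_unique": len(d.a_unique),
                              "cancer_unique": len(d.b_unique)})
        _write(pd.DataFrame(diff_rows), outdir / "differential_summary.tsv", index=False)
        results["differential"] = differential

        stage = "feature_distribution"
        dist_frames = []
        marginals = {}
        for (mark, condition), cs in sorted(consensus.items()):
            dist = feature_distribution(cs.peaks, index)
            key = f"{'hmc' if mark == '5hmC' else 'mc'}_{condition}"
            marginals[key] = feature_distribution(cs.peaks, index,
                                                  features=DYNAMICS_FEATURES)
            d = dist.reset_index()
            d.insert(0, "mark", mark)
            d.insert(1, "condition", condition)
            dist_frames.append(d)
        _write(pd.concat(dist_frames, ignore_index=True),
               outdir / "feature_distribution.tsv", index=False)
        results["feature_distribution"] = dist_frames

        stage = "expression_association"
        assoc_frames = []
        tier_tables = {}
        for condition, expr in sorted(inputs.expression.items()):
            tiers = tier_split(expr, config.n_tiers)
            tier_tables[condition] = tiers
            for mark in MARKS:
                diff = differential[mark]
                peaks = diff.a_unique if condition == "normal" else diff.b_unique
                counts = assign_peaks_to_tiers(peaks, index, tiers)
                table = association_table(counts, tiers, alpha=config.alpha)
                t = table.reset_index()
                t.insert(0, "mark", mark)
                t.insert(1, "condition", condition)
                t["n_excluded_peaks"] = counts.n_excluded
                assoc_frames.append(t)
        if assoc_frames:
            _write(pd.concat(assoc_frames, ignore_index=True),
                   outdir / "association.tsv", index=False)
        results["association"] = assoc_frames
        results["tiers"] = tier_tables

        stage = "dynamics"
        classes = classify_dynamics(
            consensus[("5hmC", "normal")].peaks, consensus[("5mC", "normal")].peaks,
            consensus[("5hmC", "cancer")].peaks, consensus[("5mC", "cancer")].peaks)
        dyn = dynamics_table(classes, index, marginals, alpha=config.alpha)
        _write(dyn, outdir / "dynamics.tsv", index=False)
        results["dynamics"] = dyn
        results["dynamics_classes"] = classes

        in_feature = pd.DataFrame(
            {c.name: feature_distribution(c.normal_peaks, index,
                                          features=DYNAMICS_FEATURES)["count"]
             for c in classes})
        class_totals = {c.name: len(c.normal_peaks) for c in classes}
        if all(v > 0 for v in class_totals.values()):
            comparison = compare_dynamic_classes(in_feature, class_totals,
                                                 alpha=config.alpha)
            _write(comparison, outdir / "class_comparison.tsv")
            results["class_comparison"] = comparison

        stage = "coincidence"
        coin_frames = []
        for condition in CONDITIONS:
            co = coincidence_regions(consensus[("5mC", condition)].peaks,
                                     consensus[("5hmC", condition)].peaks,
                                     index, cell_line=condition)
            write_bed(co.spans, outdir / f"coincidence_{condition}.bed")
            d = co.distribution.reset_index()
            d.insert(0, "condition", condition)
            d["n_coincident"] = len(co.spans)
            coin_frames.append(d)
        _write(pd.concat(coin_frames, ignore_index=True),
               outdir / "coincidence.tsv", index=False)
        results["coincidence"] = coin_frames

        stage = "background_expectation"
        if inputs.cpgs is not None and len(inputs.cpgs) > 0:
            bg = random_background_expectation(
                consensus[("5hmC", "normal")].peaks, inputs.cpgs, index,
                alpha=config.alpha)
            _write(bg, outdir / "background_expectation.tsv")
            results["background_expectation"] = bg

        stage = "enrichment"
        if inputs.gene_sets is not None:
            fg = differential["5hmC"].a_unique
            bg_regions = merge_intervals(
                list(consensus[("5hmC", "normal")].peaks)
                + list(consensus[("5hmC", "cancer")].peaks))
            if len(fg) > 0:
                enr = region_enrichment(fg, bg_regions, inputs.gene_sets, index)
                _write(enr, outdir / "enrichment.tsv", index=False)
                edges = similarity_edges(
                    enr, jaccard_threshold=config.jaccard_threshold,
                    p_max=config.enrichment_p_max,
                    fdr_max=config.enrichment_fdr_max,
                    edge_when=config.jaccard_edge_when)
                _write(edges, outdir / "enrichment_edges.tsv", index=False)
                results["enrichment"] = enr
                results["enrichment_edges"] = edges

        stage = "run_log"
        log = {
            "hydromark_version": __version__,
            "python_version": platform.python_version(),
            "seed": config.seed,
            "simulate": config.simulate,
            "alpha": config.alpha,
            "bonferroni_m": config.bonferroni_m,
            "n_tiers": config.n_tiers,
            "feature_params": asdict(config.feature_params),
            "consensus_k": {"5mC": config.consensus_k_5mc,
                            "5hmC": config.consensus_k_5hmc},
            "enrichment": {"p_max": config.enrichment_p_max,
                           "fdr_max": config.enrichment_fdr_max,
                           "jaccard_threshold": config.jaccard_threshold,
                           "jaccard_edge_when": config.jaccard_edge_when},
        }
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
        results["run_log"] = log
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
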