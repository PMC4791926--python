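"""Readers and writers for the plain-text formats the pipeline touches.

BED3/BED6/BED12 (0-based half-open), GMT gene-set collections, tab-separated
expression tables, and a simple tabular gene-model dialect
(``chrom start end name strand exon_starts exon_ends``).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, PeakSet, _dedup_longest


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line."""


def _parse_bed_line(line: str, lineno: int, path) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score: Optional[float] = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
    try:
        return GenomicInterval(chrom, start, end, strand=strand, score=score, name=name)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_bed(path, label=None) -> PeakSet:
    """Read a BED3/BED6 file into a sorted PeakSet.

    Coordinates are taken as BED-standard 0-based half-open; column 5 is
    parsed as the score when present.  Malformed lines raise ParseError
    naming the line; an empty file yields an empty set with a warning.
    """
    path = Path(path)
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            intervals.append(_parse_bed_line(line, lineno, path))
    if not intervals:
        warnings.warn(f"{path}: empty BED file", stacklevel=2)
    return PeakSet(intervals, label=label)


def write_bed(peaks: PeakSet, path) -> None:
    """Write a PeakSet as BED6 (name/score/strand filled with '.' or 0)."""
    with open(path, "w") as fh:
        for iv in peaks:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


_GENE_TSV_HEADER = ["chrom", "start", "end", "name", "strand", "exon_starts", "exon_ends"]


def _gene_from_fields(chrom, start, end, name, strand, ex_starts, ex_ends, ctx):
    if strand not in ("+", "-"):
        raise ParseError(f"{ctx}: strand must be + or -, got {strand!r}")
    try:
        exons = tuple(
            GenomicInterval(chrom, int(s), int(e))
            for s, e in zip(ex_starts, ex_ends)
        )
    except ValueError as exc:
        raise ParseError(f"{ctx}: bad exon block ({exc})") from exc
    try:
        return GeneModel(
            GenomicInterval(chrom, int(start), int(end), strand=strand, name=name),
            gene_name=name,
            exons=exons,
        )
    except ValueError as exc:
        raise ParseError(f"{ctx}: {exc}") from exc


def read_gene_models(path) -> List[GeneModel]:
    """Read gene models from BED12 or the tabular gene TSV dialect.

    Duplicate gene names are collapsed by keeping the longest transcript.
    A header line starting with ``chrom`` selects the TSV dialect; otherwise
    BED12 is assumed.
    """
    path = Path(path)
    genes: List[GeneModel] = []
    with open(path) as fh:
        first = fh.readline()
        is_tsv = first.split("\t")[0].strip() == "chrom"
        if is_tsv:
            header = first.rstrip("\n").split("\t")
            if header[: len(_GENE_TSV_HEADER)] != _GENE_TSV_HEADER:
                raise ParseError(f"{path}:1: unexpected gene TSV header {header}")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 7:
                    raise ParseError(f"{path}:{lineno}: expected 7 fields")
                ex_s = [x for x in f[5].split(",") if x]
                ex_e = [x for x in f[6].split(",") if x]
                if len(ex_s) != len(ex_e):
                    raise ParseError(f"{path}:{lineno}: exon_starts/exon_ends mismatch")
                genes.append(
                    _gene_from_fields(f[0], f[1], f[2], f[3], f[4], ex_s, ex_e,
                                      f"{path}:{lineno}")
                )
        else:
            for lineno, line in enumerate([first] + fh.readlines(), start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 12:
                    raise ParseError(f"{path}:{lineno}: BED12 needs 12 fields")
                chrom, start, end, name, _score, strand = f[:6]
                try:
                    start_i = int(start)
                    n_blocks = int(f[9])
                    sizes = [int(x) for x in f[10].split(",") if x]
                    offsets = [int(x) for x in f[11].split(",") if x]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad block fields") from exc
                if len(sizes) != n_blocks or len(offsets) != n_blocks:
                    raise ParseError(f"{path}:{lineno}: block count mismatch")
                ex_s = [start_i + o for o in offsets]
                ex_e = [start_i + o + s for o, s in zip(offsets, sizes)]
                genes.append(
                    _gene_from_fields(chrom, start, end, name, strand, ex_s, ex_e,
                                      f"{path}:{lineno}")
                )
    return _dedup_longest(genes)


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    """Write gene models in the tabular gene TSV dialect."""
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_TSV_HEADER) + "\n")
        for g in sorted(genes, key=lambda g: g.interval.sort_key()):
            ex_s = ",".join(str(e.start) for e in g.exons)
            ex_e = ",".join(str(e.end) for e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.gene_name}"
                f"\t{g.strand}\t{ex_s}\t{ex_e}\n"
            )


def read_expression(path) -> pd.Series:
    """Per-gene mean expression across replicate columns.

    Expects a TSV with a ``gene`` column and >=1 numeric replicate columns.
    Genes with all-missing values are dropped with a warning; duplicate gene
    rows are an error (probe-to-gene mapping must be resolved upstream).
    """
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ParseError(f"{path}: expected a 'gene' column")
    if df["gene"].duplicated().any():
        dups = df["gene"][df["gene"].duplicated()].unique()
        raise ParseError(f"{path}: duplicate gene rows: {list(dups)[:5]}")
    value_cols = [c for c in df.columns if c != "gene"]
    if not value_cols:
        raise ParseError(f"{path}: no replicate columns")
    values = df[value_cols].apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & df[value_cols].notna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        raise ParseError(f"{path}: non-numeric value at row {row + 2} (1-based, incl. header)")
    mean = values.mean(axis=1)
    mean.index = df["gene"]
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"{path}: dropping {int(all_missing.sum())} genes with no expression values",
            stacklevel=2,
        )
        mean = mean[~all_missing.values]
    return mean


def write_expression(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


class GeneSetCollection:
    """Named gene sets with descriptions (GMT semantics)."""

    def __init__(self, sets: Dict[str, frozenset], descriptions: Optional[Dict[str, str]] = None):
        for name, members in sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {k: frozenset(v) for k, v in sets.items()}
        self.descriptions = descriptions or {k: "" for k in sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]


def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file: name, description, then >=1 gene per line."""
    path = Path(path)
    sets: Dict[str, frozenset] = {}
    descriptions: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, desc, genes = f[0], f[1], [g for g in f[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: empty gene list")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.descriptions.get(name, '')}\t{genes}\n")
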