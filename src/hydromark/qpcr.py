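"""Relative enrichment quantification for capture-qPCR assays (delta-delta-Ct).

Each assay pairs bound (captured) Ct values with input-dilution Ct values.
The input reaction represents a known fraction of total input DNA, so its
Ct is corrected to a full-input equivalent by log2 of that fraction before
forming delta-Ct.  Fold enrichment of a target over a reference locus is
2^(-mean delta-delta-Ct), with the SD taken over per-replicate fold values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: default input dilution (0.027 % of input genomic DNA)
DEFAULT_INPUT_FRACTION = 0.00027


@dataclass(frozen=True)
class QPCRAssay:
    """Ct values (cycles) for one locus: bound capture vs. input dilution."""

    gene: str
    bound_ct: Tuple[float, ...]
    input_ct: Tuple[float, ...]
    input_fraction: float = DEFAULT_INPUT_FRACTION

    def __post_init__(self) -> None:
        if not self.bound_ct or not self.input_ct:
            raise ValueError(f"{self.gene}: need >= 1 replicate of bound and input Ct")
        if len(self.bound_ct) != len(self.input_ct):
            raise ValueError(f"{self.gene}: bound/input replicate counts differ")
        if any(ct <= 0 for ct in self.bound_ct + self.input_ct):
            raise ValueError(f"{self.gene}: Ct values must be positive")
        if not 0 < self.input_fraction <= 1:
            raise ValueError(f"{self.gene}: input fraction must be in (0, 1]")

    def delta_ct(self) -> np.ndarray:
        """Per-replicate Ct(bound) - Ct(full-input equivalent).

        A dilution holding fraction f of the input amplifies log2(1/f)
        cycles later than full input, so the full-input-equivalent Ct is
        Ct(input) + log2(f).
        """
        bound = np.asarray(self.bound_ct, dtype=float)
        inp = np.asarray(self.input_ct, dtype=float)
        return bound - (inp + np.log2(self.input_fraction))


@dataclass(frozen=True)
class DdctResult:
    fold: float
    sd: float
    ddct_mean: float
    replicate_folds: Tuple[float, ...]


def ddct_fold(target: QPCRAssay, reference: QPCRAssay) -> DdctResult:
    """Fold enrichment of target over reference by 2^(-delta-delta-Ct).

    delta-delta-Ct is formed per replicate (matched replicate structure
    required); the fold is 2 to the minus mean, and the SD is the sample
    standard deviation of the per-replicate folds.
    """
    d_t = target.delta_ct()
    d_r = reference.delta_ct()
    if len(d_t) != len(d_r):
        raise ValueError("target and reference replicate counts differ")
    ddct = d_t - d_r
    folds = np.exp2(-ddct)
    sd = float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0
    return DdctResult(
        fold=float(np.exp2(-ddct.mean())),
        sd=sd,
        ddct_mean=float(ddct.mean()),
        replicate_folds=tuple(float(f) for f in folds),
    )


def read_ct_table(path) -> Dict[str, Dict[str, QPCRAssay]]:
    """Read a Ct TSV: columns gene, role in {bound, negctrl, input},
    input_fraction, replicate, ct.

    Returns gene -> role -> QPCRAssay, where 'bound' and 'negctrl' roles
    each pair with the gene's input Ct values.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "role", "input_fraction", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: Dict[str, Dict[str, QPCRAssay]] = {}
    for gene, grp in df.groupby("gene"):
        inputs = grp[grp["role"] == "input"].sort_values("replicate")
        if inputs.empty:
            raise ValueError(f"{path}: gene {gene!r} has no input Ct rows")
        input_ct = tuple(inputs["ct"].astype(float))
        frac = float(inputs["input_fraction"].iloc[0])
        out[gene] = {}
        for role in ("bound", "negctrl"):
            rows = grp[grp["role"] == role].sort_values("replicate")
            if rows.empty:
                continue
            out[gene][role] = QPCRAssay(
                gene=gene,
                bound_ct=tuple(rows["ct"].astype(float)),
                input_ct=input_ct,
                input_fraction=frac,
            )
    return out


def fold_table(
    assays: Dict[str, Dict[str, QPCRAssay]],
    reference_gene: str,
) -> pd.DataFrame:
    """Fold enrichment of every target (bound and negative-control reaction)
    relative to the reference gene's bound assay."""
    if reference_gene not in assays or "bound" not in assays[reference_gene]:
        raise ValueError(f"reference gene {reference_gene!r} missing a bound assay")
    ref = assays[reference_gene]["bound"]
    rows = []
    for gene in sorted(assays):
        for role, assay in sorted(assays[gene].items()):
            res = ddct_fold(assay, ref)
            rows.append({"gene": gene, "role": role, "fold": res.fold,
                         "sd": res.sd, "ddct": res.ddct_mean,
                         "reference": reference_gene})
    return pd.DataFrame(rows)
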