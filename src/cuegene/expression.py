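"""RPKM normalization, EC-number aggregation and the minimum-expression filter.

Raw per-gene counts are normalized to RPKM (reads per kilobase of gene
model per million counted reads), genes are aggregated to Enzyme
Commission (EC) classes so that expression is comparable across species,
and EC classes are filtered to those expressed at >= 10 RPKM in every
sample before genome-wide marker screening.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "GeneAnnotation",
    "EC_PATTERN",
    "rpkm_normalize",
    "aggregate_by_ec",
    "filter_min_expression",
]

#: EC numbers are four dot-separated fields; trailing fields may be "-"
#: placeholders for partially classified activities.
EC_PATTERN = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


@dataclass
class CountMatrix:
    """Gene x sample raw count matrix with per-gene lengths.

    counts is a pandas DataFrame indexed by gene_id with sample columns;
    gene_lengths a Series of gene lengths in bp aligned to the same index.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, copy=False)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()].tolist()
            raise ValueError(f"missing gene lengths for: {missing[:5]}")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be > 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class GeneAnnotation:
    """Mapping gene_id -> list of EC numbers (possibly empty)."""

    ec_numbers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, ecs in self.ec_numbers.items():
            for ec in ecs:
                if not EC_PATTERN.match(ec):
                    raise ValueError(f"invalid EC number {ec!r} for gene {gene}")

    def genes_for(self, ec: str) -> list[str]:
        return [g for g, ecs in self.ec_numbers.items() if ec in ecs]


def rpkm_normalize(counts: CountMatrix) -> pd.DataFrame:
    """RPKM = count / (gene length in kb * sample total counts / 1e6).

    The per-sample denominator is the column sum of the count table
    (reads assigned to genes).  A sample with zero total counts is an
    error; it cannot be depth-normalized.
    """
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    length_kb = counts.gene_lengths.to_numpy(dtype=float) / 1e3
    per_million = totals.to_numpy(dtype=float) / 1e6
    rpkm = counts.counts.to_numpy(dtype=float) / (length_kb[:, None] * per_million[None, :])
    return pd.DataFrame(rpkm, index=counts.counts.index, columns=counts.counts.columns)


def aggregate_by_ec(expr: pd.DataFrame, annot: GeneAnnotation) -> pd.DataFrame:
    """Sum gene RPKM into EC classes (EC x sample matrix).

    A gene annotated with several EC numbers contributes its full RPKM to
    each of them; unannotated genes contribute nowhere.  Annotation rows
    for genes absent from the matrix are ignored with a warning.
    """
    absent = [g for g in annot.ec_numbers if g not in expr.index]
    if absent:
        warnings.warn(
            f"{len(absent)} annotated gene(s) absent from expression matrix "
            f"(e.g. {absent[:3]}); ignored",
            stacklevel=2,
        )
    pairs = [
        (gene, ec)
        for gene, ecs in annot.ec_numbers.items()
        if gene in expr.index
        for ec in ecs
    ]
    if not pairs:
        raise ValueError("no annotated gene present in the expression matrix")
    genes, ecs = zip(*pairs)
    stacked = expr.loc[list(genes)].copy()
    stacked.index = pd.Index(ecs, name="ec_id")
    out = stacked.groupby(level=0, sort=True).sum()
    return out


def filter_min_expression(ecmat: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Keep EC rows whose minimum expression over samples is >= threshold.

    The bound is inclusive ("at least"); row order is preserved and the
    operation is idempotent.  An empty result is allowed.
    """
    if ecmat.empty:
        raise ValueError("ecmat must be nonempty")
    keep = ecmat.min(axis=1) >= threshold
    return ecmat.loc[keep]
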