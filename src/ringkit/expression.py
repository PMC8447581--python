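"""Drought-vs-control fold changes and the threshold DEG screen.

Expression is compared between water-stress (WS) and well-watered (WW)
treatments per genotype across timepoints T1-T4.  A gene is differential at
a timepoint when |log2(WS/WW)| strictly exceeds the threshold (default 1).
Zeros follow a documented convention rather than a pseudocount: WS>0, WW=0
gives +inf (differential); WS=0, WW>0 gives -inf (differential); both zero
is undefined and never differential.  A ``pseudocount`` option is available
for users who prefer finite values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FoldChangeMatrix",
    "log2_fold_change",
    "call_degs",
    "multi_period_intersection",
    "VennReport",
]

CONDITIONS = ("WS", "WW")


@dataclass
class ExpressionMatrix:
    """Long-form expression values: gene x (genotype, condition, timepoint)."""

    data: pd.DataFrame  # columns: gene, genotype, condition, timepoint, value

    REQUIRED = ("gene", "genotype", "condition", "timepoint", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"expression table missing columns: {missing}")
        if (self.data["value"] < 0).any():
            raise ValueError("negative expression values")
        bad = set(self.data["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t")
        if set(cls.REQUIRED) <= set(df.columns):
            return cls(df)
        # wide form: gene + <genotype>_<condition>_<timepoint> columns
        long = df.melt(id_vars=["gene"], var_name="sample", value_name="value")
        parts = long["sample"].str.split("_", expand=True)
        long["genotype"], long["condition"], long["timepoint"] = (
            parts[0], parts[1], parts[2],
        )
        return cls(long[list(cls.REQUIRED)])

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.data["gene"]))

    @property
    def timepoints(self) -> list[str]:
        return sorted(set(self.data["timepoint"]))

    @property
    def genotypes(self) -> list[str]:
        return sorted(set(self.data["genotype"]))


@dataclass
class FoldChangeMatrix:
    """log2(WS/WW) per gene and timepoint for one genotype.

    Cells are finite, +/-inf (one condition zero) or NaN (both zero).
    """

    genotype: str
    values: pd.DataFrame  # index gene, columns timepoints
    expressed: pd.Series  # bool per gene: nonzero in at least one sample


def log2_fold_change(
    matrix: ExpressionMatrix, genotype: str, pseudocount: float = 0.0
) -> FoldChangeMatrix:
    """Per-gene, per-timepoint log2(WS/WW) for one genotype."""
    sub = matrix.data[matrix.data["genotype"] == genotype]
    if sub.empty:
        raise ValueError(f"genotype {genotype!r} not present")
    wide = sub.pivot_table(
        index="gene", columns=["condition", "timepoint"], values="value",
        aggfunc="mean", sort=False,
    )
    wide = wide.reindex(index=list(dict.fromkeys(sub["gene"])))
    tps = sorted({tp for _, tp in wide.columns})
    out = pd.DataFrame(index=wide.index, columns=tps, dtype=float)
    for tp in tps:
        ws = wide[("WS", tp)] + pseudocount
        ww = wide[("WW", tp)] + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.log2(ws.to_numpy() / ww.to_numpy())
        # 0/0 -> NaN (undefined), x/0 -> +inf, 0/x -> -inf by IEEE rules
        out[tp] = fc
    expressed = (
        sub.groupby("gene", sort=False)["value"].max() > 0
    ).reindex(out.index, fill_value=False)
    return FoldChangeMatrix(genotype=genotype, values=out, expressed=expressed)


def call_degs(
    fc: FoldChangeMatrix, threshold: float = 1.0
) -> dict[str, set[str]]:
    """Per-timepoint sets of genes with |log2 FC| strictly above threshold.

    Undefined (NaN) cells are never differential; infinite cells are.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    sets: dict[str, set[str]] = {}
    for tp in fc.values.columns:
        col = fc.values[tp]
        mask = col.abs() > threshold  # NaN compares False
        sets[tp] = set(col.index[mask.fillna(False)])
    return sets


@dataclass
class VennReport:
    membership_counts: Mapping[str, int]  # gene -> number of sets containing it
    region_counts: Mapping[frozenset, int]  # exact-region cardinalities
    at_least_k: set = field(default_factory=set)
    k: int = 0


def multi_period_intersection(
    deg_sets: Mapping[str, set[str]] | Sequence[set[str]], k: int = 3
) -> VennReport:
    """Genes differential in >= k periods, plus every Venn region count.

    Region keys are frozensets of set labels; a gene belongs to exactly one
    region (the labels of all sets containing it).
    """
    if isinstance(deg_sets, Mapping):
        labelled = dict(deg_sets)
    else:
        labelled = {f"set{i + 1}": s for i, s in enumerate(deg_sets)}
    if not labelled:
        raise ValueError("at least one DEG set required")
    union = set().union(*labelled.values())
    membership: dict[str, int] = {}
    regions: dict[frozenset, int] = {}
    for labels in _nonempty_subsets(list(labelled)):
        regions[frozenset(labels)] = 0
    for gene in union:
        labels = frozenset(l for l, s in labelled.items() if gene in s)
        membership[gene] = len(labels)
        regions[labels] += 1
    return VennReport(
        membership_counts=membership,
        region_counts=regions,
        at_least_k={g for g, n in membership.items() if n >= k},
        k=k,
    )


def _nonempty_subsets(labels: list[str]):
    for r in range(1, len(labels) + 1):
        yield from combinations(labels, r)
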