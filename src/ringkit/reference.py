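"""Packaged reference tables for the grapevine RING C3H2C3 family.

Two small curated tables from the published genome-wide survey of the
grapevine (Vitis vinifera) family ship with the package:

* the family table — the 143 members with transcript id, chromosome,
  genomic coordinates, protein length, molecular weight and pI; and
* the duplicate-pair table — the nine paralogous pairs with their reported
  Ka, Ks and duplication class.

They serve as real-data inputs for the summary statistics that are pure
arithmetic on published values (chromosome distributions, selection
summaries) and as shape references for the synthetic generators.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .annotation import GeneModel
from .kaks import DupPair

__all__ = ["load_family_table", "load_duplicate_pairs", "family_gene_models"]


def _data(name: str) -> Path:
    ref = resources.files("ringkit.data") / name
    with resources.as_file(ref) as p:
        return p


def load_family_table() -> pd.DataFrame:
    """The 143-member grapevine family table."""
    return pd.read_csv(_data("grapevine_rchc_family.tsv"), sep="\t")


def family_gene_models() -> list[GeneModel]:
    """Family table rows as GeneModel records (exon structure unknown)."""
    df = load_family_table()
    return [
        GeneModel(
            gene_id=str(r["gene_name"]),
            chromosome=str(r["chromosome"]),
            start=int(r["start"]),
            end=int(r["end"]),
            strand="+",
            exons=(),
            transcript_id=str(r["transcript_id"]),
        )
        for _, r in df.iterrows()
    ]


def load_duplicate_pairs() -> list[DupPair]:
    """The nine reported paralogous pairs with Ka, Ks and class.

    Identity/aligned-fraction are not part of the published record and are
    reported as 100 by convention (the pairs passed the study's screen).
    """
    df = pd.read_csv(_data("grapevine_rchc_duplicates.tsv"), sep="\t")
    return [
        DupPair(
            gene_a=str(r["gene_a"]),
            gene_b=str(r["gene_b"]),
            identity=100.0,
            aligned_fraction=100.0,
            dup_class=str(r["dup_class"]),
            ka=float(r["ka"]),
            ks=float(r["ks"]),
            ratio=float(r["ka"]) / float(r["ks"]),
        )
        for _, r in df.iterrows()
    ]
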