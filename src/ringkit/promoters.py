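"""Promoter extraction and cis-acting element census.

Promoters are the 2 kb immediately 5' of the translation start, strand-aware.
Elements are short IUPAC-degenerate motifs grouped into seven functional
categories (light response, hormone response, growth and development
response, stress response, enhanced promoter, binding site, other).  The
shipped dictionary carries literature-standard patterns for the commonly
reported plant elements (ABRE, ARE, G-box, MBS, ...) and is fully
user-replaceable; different dictionaries will of course yield different
counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .annotation import GeneModel

__all__ = [
    "CATEGORIES",
    "ElementDef",
    "CisElementHit",
    "PromoterSeq",
    "load_element_table",
    "default_elements",
    "extract_promoter",
    "scan_elements",
    "summarize_categories",
]

CATEGORIES = (
    "light response",
    "hormone response",
    "growth and development response",
    "stress response",
    "enhanced promoter cis-acting",
    "binding site cis-acting",
    "other functional cis-acting",
)

_IUPAC = {k: set(v) for k, v in ambiguous_dna_values.items()}


@dataclass(frozen=True)
class ElementDef:
    name: str
    category: str
    pattern: str  # IUPAC-degenerate, given on the forward strand

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"{self.name}: empty pattern")
        bad = set(self.pattern.upper()) - set(_IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC characters {sorted(bad)}")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    @property
    def regex(self) -> re.Pattern:
        return re.compile(
            "".join(
                c if len(_IUPAC[c]) == 1 else "[" + "".join(sorted(_IUPAC[c])) + "]"
                for c in self.pattern
            )
        )


@dataclass(frozen=True)
class CisElementHit:
    promoter_id: str
    element: str
    category: str
    strand: str  # '+' or '-'
    offset: int  # 0-based on the promoter's forward orientation


@dataclass(frozen=True)
class PromoterSeq:
    gene_id: str
    sequence: str
    truncated: bool = False


def load_element_table(path: str | Path) -> list[ElementDef]:
    """Read an element dictionary TSV with columns name, category, pattern."""
    df = pd.read_csv(path, sep="\t")
    return [
        ElementDef(str(r["name"]), str(r["category"]), str(r["pattern"]))
        for _, r in df.iterrows()
    ]


def default_elements() -> list[ElementDef]:
    """The packaged element dictionary."""
    ref = resources.files("ringkit.data") / "cis_elements.tsv"
    with resources.as_file(ref) as p:
        return load_element_table(p)


def extract_promoter(
    model: GeneModel, genome: Mapping[str, str], length: int = 2000
) -> PromoterSeq:
    """Strand-aware upstream sequence, 5' of the translation start.

    Plus strand: the ``length`` bases ending just before the gene start.
    Minus strand: the reverse complement of the ``length`` bases just after
    the gene end.  Truncated (and flagged) at the contig edge.
    """
    if model.chromosome not in genome:
        raise KeyError(f"chromosome {model.chromosome!r} not in genome")
    contig = genome[model.chromosome].upper()
    if model.strand == "-":
        lo = model.end  # 0-based slice start = first base after gene end
        hi = min(len(contig), model.end + length)
        seq = str(Seq(contig[lo:hi]).reverse_complement())
        truncated = hi - lo < length
    else:
        hi = model.start - 1
        lo = max(0, hi - length)
        seq = contig[lo:hi]
        truncated = hi - lo < length
    return PromoterSeq(model.gene_id, seq, truncated)


def scan_elements(
    promoter: PromoterSeq | str,
    dictionary: Sequence[ElementDef] | None = None,
    promoter_id: str | None = None,
) -> list[CisElementHit]:
    """All (overlapping) element occurrences on both strands.

    Minus-strand occurrences are reported at their forward-orientation
    offset, i.e. the 0-based start of the matched window on the promoter as
    given.  A palindromic pattern therefore yields one hit per strand at the
    same offset.
    """
    if isinstance(promoter, str):
        promoter = PromoterSeq(promoter_id or "promoter", promoter)
    dictionary = default_elements() if dictionary is None else dictionary
    seq = promoter.sequence.upper()
    rc = str(Seq(seq).reverse_complement())
    L = len(seq)
    hits: list[CisElementHit] = []
    # lookahead regex so overlapping occurrences are all reported
    for el in dictionary:
        rx = re.compile("(?=(" + el.regex.pattern + "))")
        m_len = len(el.pattern)
        for m in rx.finditer(seq):
            hits.append(CisElementHit(promoter.gene_id, el.name, el.category, "+", m.start()))
        for m in rx.finditer(rc):
            hits.append(
                CisElementHit(
                    promoter.gene_id, el.name, el.category, "-", L - m.start() - m_len
                )
            )
    hits.sort(key=lambda h: (h.offset, h.element, h.strand))
    return hits


def summarize_categories(
    hits: Iterable[CisElementHit],
    genes: Sequence[str],
    dictionary: Sequence[ElementDef] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene element counts and per-element / per-category prevalence.

    Returns (counts, prevalence): ``counts`` is a gene x element occurrence
    matrix; ``prevalence`` has, per element, the number of genes with at
    least one occurrence and that number as a percentage of all genes
    (rounded to the nearest integer), plus the element's category.
    """
    dictionary = default_elements() if dictionary is None else dictionary
    elements = [el.name for el in dictionary]
    cat_of = {el.name: el.category for el in dictionary}
    counts = pd.DataFrame(0, index=list(genes), columns=elements, dtype=int)
    for h in hits:
        if h.promoter_id in counts.index and h.element in counts.columns:
            counts.loc[h.promoter_id, h.element] += 1
    n_genes = len(counts.index)
    rows = []
    for el in elements:
        n_with = int((counts[el] > 0).sum())
        rows.append(
            {
                "element": el,
                "category": cat_of[el],
                "genes_with_element": n_with,
                "prevalence_pct": round(100.0 * n_with / n_genes) if n_genes else 0,
                "total_occurrences": int(counts[el].sum()),
            }
        )
    prev_cols = [
        "element", "category", "genes_with_element", "prevalence_pct",
        "total_occurrences",
    ]
    prevalence = pd.DataFrame(rows, columns=prev_cols).set_index("element")
    return counts, prevalence
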