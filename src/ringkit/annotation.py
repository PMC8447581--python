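"""Gene models from GFF3: structure statistics, chromosome maps, family naming.

Family members are named by genomic position: chromosomes in natural order
(chr1, chr2, ..., chr19, then unanchored scaffolds), genes by start
coordinate within each chromosome, numbered prefix1..prefixN.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "load_gene_models",
    "intron_stats",
    "IntronStats",
    "assign_family_names",
    "chromosome_distribution",
    "natural_chromosome_key",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene with its selected transcript's exon structure (1-based bp)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    transcript_id: str = ""
    family_name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        ex = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a1, b1), (a2, b2) in zip(ex, ex[1:]):
            if a2 <= b1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", ex)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def intron_count(self) -> int:
        return max(0, len(self.exons) - 1)


def _validate_gff_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise ValueError(f"malformed GFF3 at line {lineno}: expected 9 columns")


def load_gene_models(gff3: str | Path) -> list[GeneModel]:
    """Parse gene models from a GFF3 path or GFF3 text.

    One model per gene, using the transcript with the longest total CDS
    (ties broken by lexicographically smallest transcript id).  Intron
    structure comes from exon features; when a transcript has only CDS
    features those stand in for exons (logged).
    """
    text = str(gff3)
    if isinstance(gff3, Path) or ("\n" not in text and Path(text).exists()):
        text = Path(gff3).read_text()
    _validate_gff_lines(text)
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            logger.warning("gene %s has no mRNA children; skipped", gene.id)
            continue

        def cds_len(t) -> int:
            return sum(c.end - c.start + 1 for c in db.children(t, featuretype="CDS"))

        mrnas.sort(key=lambda t: (-cds_len(t), t.id))
        best = mrnas[0]
        exons = [(e.start, e.end) for e in db.children(best, featuretype="exon")]
        if not exons:
            exons = [(c.start, c.end) for c in db.children(best, featuretype="CDS")]
            if exons:
                logger.info(
                    "transcript %s: no exon features; CDS intervals used", best.id
                )
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=tuple(exons),
                transcript_id=best.id,
            )
        )
    return models


@dataclass
class IntronStats:
    histogram: Counter
    pct_at_most_k: float
    k: int
    max_intron_count: int
    max_intron_gene: str
    zero_intron_count: int
    zero_intron_genes: list[str] = field(default_factory=list)


def intron_stats(models: Sequence[GeneModel], k: int = 2) -> IntronStats:
    """Distribution of intron counts; share with <= k introns (% to 2 dp)."""
    if not models:
        raise ValueError("no gene models: no intron statistics can be computed")
    hist = Counter(m.intron_count for m in models)
    n_low = sum(n for c, n in hist.items() if c <= k)
    max_model = max(models, key=lambda m: (m.intron_count, m.gene_id))
    zeros = [m.gene_id for m in models if m.intron_count == 0]
    return IntronStats(
        histogram=hist,
        pct_at_most_k=round(100.0 * n_low / len(models), 2),
        k=k,
        max_intron_count=max_model.intron_count,
        max_intron_gene=max_model.gene_id,
        zero_intron_count=len(zeros),
        zero_intron_genes=zeros,
    )


_NUM_RE = re.compile(r"(\d+)$")


def natural_chromosome_key(chrom: str) -> tuple[int, int, str]:
    """Sort key: numbered chromosomes numerically, unanchored scaffolds last."""
    m = _NUM_RE.search(chrom)
    if m and not re.search(r"un", chrom, re.IGNORECASE):
        return (0, int(m.group(1)), chrom)
    return (1, 0, chrom)


def assign_family_names(
    models: Iterable[GeneModel], prefix: str = "RCHC"
) -> list[GeneModel]:
    """Name members by chromosomal position: prefix1..prefixN.

    Sorting is by chromosome in natural order, then by start coordinate;
    the result is independent of input order.
    """
    models = list(models)
    ids = [m.gene_id for m in models]
    dupes = {g for g, n in Counter(ids).items() if n > 1}
    if dupes:
        raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
    ordered = sorted(
        models, key=lambda m: (natural_chromosome_key(m.chromosome), m.start, m.gene_id)
    )
    return [
        replace(m, family_name=f"{prefix}{i}") for i, m in enumerate(ordered, start=1)
    ]


def chromosome_distribution(models: Iterable[GeneModel]) -> dict[str, int]:
    """Gene counts per chromosome, keyed in natural chromosome order."""
    ctr = Counter(m.chromosome for m in models)
    return {c: ctr[c] for c in sorted(ctr, key=natural_chromosome_key)}
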