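"""End-to-end orchestration: identification -> domain census -> duplication ->
cis-elements -> expression, with TSV reports and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
from Bio import SeqIO

from . import __version__
from .annotation import assign_family_names, intron_stats, load_gene_models
from .domain_scan import (
    ProteinRecord,
    SpacerBounds,
    domain_length_distribution,
    scan_c3h2c3,
    spacer_census,
)
from .expression import ExpressionMatrix, call_degs, log2_fold_change, multi_period_intersection
from .kaks import annotate_kaks, classify_duplication, detect_duplicate_pairs, selection_summary
from .physchem import physchem
from .promoters import default_elements, extract_promoter, load_element_table, scan_elements, summarize_categories

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_family_table"]


@dataclass
class PipelineConfig:
    """Paths, stage toggles and parameters for one pipeline run."""

    proteome: str | None = None
    cds: str | None = None
    genome: str | None = None
    gff: str | None = None
    expression: str | None = None
    element_table: str | None = None

    outdir: str = "ringkit_out"
    prefix: str = "RCHC"
    bounds: SpacerBounds = field(default_factory=SpacerBounds)
    flank: int = 4
    identity_threshold: float = 75.0
    promoter_length: int = 2000
    genotype: str | None = None
    deg_threshold: float = 1.0
    min_periods: int = 3
    seed: int = 0

    stages: tuple[str, ...] = ("scan", "physchem", "annotate", "dup", "cre", "degs")

    def validate(self) -> None:
        needs = {
            "scan": ["proteome"], "physchem": ["proteome"], "annotate": ["gff"],
            "dup": ["cds", "gff"], "cre": ["genome", "gff"], "degs": ["expression"],
        }
        for stage in self.stages:
            for attr in needs[stage]:
                path = getattr(self, attr)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(
                        f"stage {stage!r} requires existing input {attr!r} (got {path})"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "bounds" in raw and isinstance(raw["bounds"], dict):
            raw["bounds"] = SpacerBounds.from_dict(raw["bounds"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_family_table(records: list[dict], path: str | Path) -> pd.DataFrame:
    """Write the family summary table (one row per member).

    Columns: gene_name, sequence_id, chromosome, localization (start~end),
    protein_length_aa, molecular_weight_kda (2 dp), pi (2 dp).
    """
    cols = [
        "gene_name", "sequence_id", "chromosome", "localization",
        "protein_length_aa", "molecular_weight_kda", "pi",
    ]
    missing = [
        r.get("gene_name", "?") for r in records if any(c not in r for c in cols)
    ]
    if missing:
        raise ValueError(f"incomplete rows for: {missing}")
    df = pd.DataFrame(records, columns=cols)
    df["molecular_weight_kda"] = df["molecular_weight_kda"].map(lambda v: f"{v:.2f}")
    df["pi"] = df["pi"].map(lambda v: f"{v:.2f}")
    df.to_csv(path, sep="\t", index=False)
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and write every report to ``config.outdir``.

    Returns a result bundle (in-memory objects per stage) and writes a run
    manifest with parameters, input checksums and per-stage record counts.
    The run is deterministic given inputs and parameters.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    counts: dict[str, dict] = {}

    proteins: dict[str, ProteinRecord] = {}
    if config.proteome and ("scan" in config.stages or "physchem" in config.stages):
        for pid, seq in _read_fasta(config.proteome).items():
            proteins[pid] = ProteinRecord(pid, seq)

    hits = []
    if "scan" in config.stages:
        for p in proteins.values():
            hits.extend(scan_c3h2c3(p, config.bounds))
        rows = [
            {
                "protein_id": h.protein_id,
                **{f"p{i + 1}": pos + 1 for i, pos in enumerate(h.positions)},
                **{f"s{i + 1}": s for i, s in enumerate(h.spacers)},
                "span": h.span,
            }
            for h in hits
        ]
        pd.DataFrame(
            rows,
            columns=["protein_id"] + [f"p{i}" for i in range(1, 9)]
            + [f"s{i}" for i in range(1, 8)] + ["span"],
        ).to_csv(outdir / "domain_hits.tsv", sep="\t", index=False)
        if hits:
            census = spacer_census(hits)
            pd.DataFrame(
                {
                    "gap": [f"g{i + 1}" for i in range(7)],
                    "min": census.gap_min,
                    "max": census.gap_max,
                }
            ).to_csv(outdir / "spacer_census.tsv", sep="\t", index=False)
            spans, pct = domain_length_distribution(hits)
            results["span_pct_41_42"] = pct
            results["census"] = census
        results["hits"] = hits
        counts["scan"] = {"proteins_in": len(proteins), "hits_out": len(hits)}

    if "physchem" in config.stages:
        pc_rows = []
        for p in proteins.values():
            pc = physchem(p.sequence)
            pc_rows.append(
                {
                    "id": p.id,
                    "length": pc.length,
                    "molecular_weight_kda": f"{pc.molecular_weight / 1000:.2f}",
                    "pi": f"{pc.pI:.2f}",
                }
            )
        pd.DataFrame(pc_rows).to_csv(outdir / "physchem.tsv", sep="\t", index=False)
        results["physchem"] = pc_rows
        counts["physchem"] = {"proteins_in": len(proteins), "rows_out": len(pc_rows)}

    models = []
    if config.gff and ("annotate" in config.stages or "dup" in config.stages or "cre" in config.stages):
        models = assign_family_names(load_gene_models(config.gff), config.prefix)

    if "annotate" in config.stages:
        pd.DataFrame(
            [
                {
                    "gene_id": m.gene_id, "family_name": m.family_name,
                    "chromosome": m.chromosome, "start": m.start, "end": m.end,
                    "strand": m.strand, "exon_count": m.exon_count,
                    "intron_count": m.intron_count,
                }
                for m in models
            ]
        ).to_csv(outdir / "gene_models.tsv", sep="\t", index=False)
        results["models"] = models
        results["intron_stats"] = intron_stats(models)
        counts["annotate"] = {"genes_out": len(models)}
        if proteins:
            fam_rows = []
            for m in models:
                if m.gene_id not in proteins:
                    continue
                pc = physchem(proteins[m.gene_id].sequence)
                fam_rows.append(
                    {
                        "gene_name": m.family_name,
                        "sequence_id": m.transcript_id or m.gene_id,
                        "chromosome": m.chromosome,
                        "localization": f"{m.start}~{m.end}",
                        "protein_length_aa": pc.length,
                        "molecular_weight_kda": pc.molecular_weight / 1000,
                        "pi": pc.pI,
                    }
                )
            write_family_table(fam_rows, outdir / "family_table.tsv")
            results["family_table_rows"] = fam_rows

    if "dup" in config.stages:
        cds_map = _read_fasta(config.cds)
        pairs = detect_duplicate_pairs(models, cds_map, config.identity_threshold)
        pairs = [annotate_kaks(p, cds_map) for p in pairs]
        from dataclasses import replace

        pairs = [
            replace(p, dup_class=classify_duplication(p, models)) for p in pairs
        ]
        pd.DataFrame(
            [
                {
                    "gene_a": p.gene_a, "gene_b": p.gene_b,
                    "identity_pct": round(p.identity, 2),
                    "ka": None if p.ka is None else round(p.ka, 3),
                    "ks": None if p.ks is None else round(p.ks, 3),
                    "ka_ks": None if p.ratio is None else round(p.ratio, 3),
                    "duplicate_type": p.dup_class,
                }
                for p in pairs
            ]
        ).to_csv(outdir / "duplicate_pairs.tsv", sep="\t", index=False)
        results["pairs"] = pairs
        results["selection_summary"] = selection_summary(pairs)
        counts["dup"] = {"genes_in": len(models), "pairs_out": len(pairs)}

    if "cre" in config.stages:
        genome = _read_fasta(config.genome)
        dictionary = (
            load_element_table(config.element_table)
            if config.element_table
            else default_elements()
        )
        all_hits = []
        gene_names = []
        for m in models:
            prom = extract_promoter(m, genome, config.promoter_length)
            gene_names.append(m.gene_id)
            all_hits.extend(scan_elements(prom, dictionary))
        counts_df, prevalence = summarize_categories(all_hits, gene_names, dictionary)
        counts_df.to_csv(outdir / "element_counts.tsv", sep="\t")
        prevalence.to_csv(outdir / "element_prevalence.tsv", sep="\t")
        pd.DataFrame(
            [
                {
                    "promoter_id": h.promoter_id, "element": h.element,
                    "category": h.category, "strand": h.strand, "offset": h.offset + 1,
                }
                for h in all_hits
            ]
        ).to_csv(outdir / "element_hits.tsv", sep="\t", index=False)
        results["element_counts"] = counts_df
        results["element_prevalence"] = prevalence
        counts["cre"] = {"promoters_in": len(gene_names), "hits_out": len(all_hits)}

    if "degs" in config.stages:
        matrix = ExpressionMatrix.from_tsv(config.expression)
        genotypes = [config.genotype] if config.genotype else matrix.genotypes
        deg_report = {}
        for genotype in genotypes:
            fc = log2_fold_change(matrix, genotype)
            fc.values.to_csv(outdir / f"fold_change_{genotype}.tsv", sep="\t")
            sets = call_degs(fc, config.deg_threshold)
            venn = multi_period_intersection(sets, config.min_periods)
            deg_report[genotype] = {"fc": fc, "deg_sets": sets, "venn": venn}
            json_out = {
                "genotype": genotype,
                "deg_sets": {tp: sorted(s) for tp, s in sets.items()},
                "venn_regions": {
                    "|".join(sorted(k)): v for k, v in venn.region_counts.items()
                },
                "at_least_k": sorted(venn.at_least_k),
                "k": venn.k,
            }
            (outdir / f"degs_{genotype}.json").write_text(
                json.dumps(json_out, indent=1, sort_keys=True)
            )
        results["degs"] = deg_report
        counts["degs"] = {
            "genes_in": len(matrix.genes),
            "genotypes": len(genotypes),
        }

    manifest = {
        "version": __version__,
        "parameters": {
            "prefix": config.prefix,
            "bounds": list(config.bounds.gaps),
            "identity_threshold": config.identity_threshold,
            "promoter_length": config.promoter_length,
            "deg_threshold": config.deg_threshold,
            "min_periods": config.min_periods,
            "seed": config.seed,
            "stages": list(config.stages),
        },
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (
                ("proteome", config.proteome), ("cds", config.cds),
                ("genome", config.genome), ("gff", config.gff),
                ("expression", config.expression),
            )
            if p is not None and Path(p).exists()
        },
        "stage_counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results
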