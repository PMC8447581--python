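"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is deterministic given (parameters, seed).  A master seed
fans out to per-generator child streams through numpy's SeedSequence with a
fixed spawn key per generator, so adding a generator never perturbs the
streams of the others.  Generators emulate the shape of a genome-wide
gene-family study — proteins with planted zinc-finger domains, paralogous
CDS pairs evolved under a chosen dN/dS, promoters with planted cis-elements,
gene models with known intron counts, and drought/control expression
matrices with planted fold-change structure — without mimicking any real
genome's composition.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .domain_scan import (
    AMINO_ACIDS,
    LIGAND_RESIDUES,
    ProteinRecord,
    RingDomainHit,
    SpacerBounds,
    enumerate_assignments,
)
from .expression import ExpressionMatrix
from .kaks import CODON_TO_AA, ng86_kaks
from .promoters import ElementDef, PromoterSeq, default_elements, scan_elements

__all__ = [
    "child_rng",
    "gen_proteome",
    "evolve_cds_pair",
    "gen_promoters",
    "gen_expression",
    "gen_gff",
    "write_bundle",
]

# fixed spawn keys: appending new generators must not renumber existing ones
_SPAWN_KEYS = {
    "proteome": 1,
    "cds": 2,
    "promoters": 3,
    "expression": 4,
    "gff": 5,
    "bundle": 6,
}

_NUCS = "ACGT"
_NON_LIGAND = "".join(aa for aa in AMINO_ACIDS if aa not in "CH")
_SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")


def child_rng(seed: int, generator: str) -> np.random.Generator:
    """Child random stream for one generator, derived from the master seed."""
    key = _SPAWN_KEYS[generator]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------


def _random_protein(rng: np.random.Generator, length: int, freqs: dict | None) -> str:
    if freqs is None:
        return "".join(rng.choice(list(AMINO_ACIDS), size=length))
    letters = sorted(freqs)
    p = np.array([freqs[aa] for aa in letters], dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(letters, size=length, p=p))


def _build_domain(rng: np.random.Generator, bounds: SpacerBounds) -> tuple[str, tuple]:
    spacers = tuple(int(rng.integers(lo, hi + 1)) for lo, hi in bounds.gaps)
    parts = [LIGAND_RESIDUES[0]]
    for lig, s in zip(LIGAND_RESIDUES[1:], spacers):
        parts.append("".join(rng.choice(list(_NON_LIGAND), size=s)))
        parts.append(lig)
    return "".join(parts), spacers


def gen_proteome(
    n_proteins: int,
    n_domains: int,
    bounds: SpacerBounds | None = None,
    background_freqs: dict | None = None,
    seed: int = 0,
    length_range: tuple[int, int] = (150, 400),
    max_tries: int = 200,
) -> tuple[list[ProteinRecord], dict]:
    """Proteins, the first ``n_domains`` of which carry one planted domain.

    Background sequences are rejection-sampled until they contain no valid
    ligand assignment; domain-bearing proteins are rejection-sampled until
    the planted assignment is the only valid one, so scanner recovery can be
    asserted exactly.
    """
    if n_domains > n_proteins:
        raise ValueError("n_domains cannot exceed n_proteins")
    bounds = bounds or SpacerBounds()
    if bounds.min_span > length_range[1]:
        raise ValueError("length_range too short for the requested spacer bounds")
    rng = child_rng(seed, "proteome")
    proteins: list[ProteinRecord] = []
    truth: dict = {"seed": seed, "proteins": {}}
    for i in range(n_proteins):
        pid = f"syn{i + 1:04d}"
        plant = i < n_domains
        for _ in range(max_tries):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            if plant:
                domain, spacers = _build_domain(rng, bounds)
                if len(domain) > length:
                    continue
                bg = _random_protein(rng, length - len(domain), background_freqs)
                pos = int(rng.integers(0, len(bg) + 1))
                seq = bg[:pos] + domain + bg[pos:]
                rec = ProteinRecord(pid, seq, "synthetic domain-bearing protein")
                planted = [pos]
                for s in spacers:
                    planted.append(planted[-1] + s + 1)
                if enumerate_assignments(rec, bounds) == [tuple(planted)]:
                    proteins.append(rec)
                    truth["proteins"][pid] = {
                        "positions": planted,
                        "spacers": list(spacers),
                        "span": planted[-1] - planted[0] + 1,
                    }
                    break
            else:
                seq = _random_protein(rng, length, background_freqs)
                rec = ProteinRecord(pid, seq, "synthetic background protein")
                if not enumerate_assignments(rec, bounds):
                    proteins.append(rec)
                    truth["proteins"][pid] = None
                    break
        else:
            raise RuntimeError(f"could not generate protein {pid} in {max_tries} tries")
    return proteins, truth


# ---------------------------------------------------------------------------
# paralogous CDS pairs under a chosen omega
# ---------------------------------------------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(_SENSE_CODONS, size=n_codons))


def evolve_cds_pair(
    ancestor_len_codons: int,
    omega: float,
    target_ks: float,
    kappa: float = 2.0,
    seed: int = 0,
    max_proposals: int = 2_000_000,
) -> tuple[str, str, dict]:
    """An ancestor CDS and a copy evolved until its NG86 Ks reaches target.

    Single-nucleotide proposals with transition:transversion ratio ``kappa``
    are accepted always when synonymous, with probability min(1, omega) when
    nonsynonymous, and rejected when they would create a stop codon.  The
    running NG86 Ks between ancestor and copy is the stopping bookkeeping.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if not 0 <= target_ks < 2.0:
        raise ValueError("target_ks must sit below Jukes-Cantor saturation")
    rng = child_rng(seed, "cds")
    anc = _random_cds(rng, ancestor_len_codons)
    cur = list(anc)
    truth = {
        "omega": omega, "kappa": kappa, "target_ks": target_ks, "seed": seed,
        "n_codons": ancestor_len_codons, "accepted_syn": 0, "accepted_nonsyn": 0,
    }
    if target_ks == 0.0:
        truth.update(ks=0.0, ka=0.0)
        return anc, anc, truth

    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    ks = 0.0
    ka = 0.0
    accepted = 0
    check_every = 8  # Ks moves by ~1/S per change; checking in blocks is safe
    for _ in range(max_proposals):
        site = int(rng.integers(0, len(cur)))
        old = cur[site]
        # transition with weight kappa, each transversion weight 1
        u = rng.random() * (kappa + 2.0)
        if u < kappa:
            new = transitions[old]
        else:
            tvs = [n for n in _NUCS if n != old and n != transitions[old]]
            new = tvs[0] if u < kappa + 1.0 else tvs[1]
        ci = site // 3
        codon_old = "".join(cur[3 * ci : 3 * ci + 3])
        codon_new = codon_old[: site % 3] + new + codon_old[site % 3 + 1 :]
        if CODON_TO_AA[codon_new] == "*":
            continue
        syn = CODON_TO_AA[codon_new] == CODON_TO_AA[codon_old]
        if not syn and rng.random() >= min(1.0, omega):
            continue
        cur[site] = new
        truth["accepted_syn" if syn else "accepted_nonsyn"] += 1
        accepted += 1
        if accepted % check_every:
            continue
        res = ng86_kaks((anc, "".join(cur)))
        ks = res.ks if res.ks is not None else float("inf")
        if ks >= target_ks:
            break
    else:
        raise RuntimeError("proposal budget exhausted before reaching target Ks")
    res = ng86_kaks((anc, "".join(cur)))
    ks = res.ks if res.ks is not None else float("inf")
    ka = res.ka if res.ka is not None else 0.0
    truth.update(ks=ks, ka=ka)
    return anc, "".join(cur), truth


# ---------------------------------------------------------------------------
# promoters with planted elements
# ---------------------------------------------------------------------------

from Bio.Data.IUPACData import ambiguous_dna_values as _AMB
from Bio.Seq import Seq as _Seq


def _realize_pattern(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        c if len(_AMB[c]) == 1 else _AMB[c][int(rng.integers(0, len(_AMB[c])))]
        for c in pattern
    )


def _scrub_background(
    rng: np.random.Generator, seq: list[str], dictionary: Sequence[ElementDef],
    max_rounds: int = 300,
) -> bool:
    """Mutate positions until no dictionary pattern matches either strand."""
    for _ in range(max_rounds):
        hits = scan_elements("".join(seq), dictionary)
        if not hits:
            return True
        for h in hits:
            w = len(next(e for e in dictionary if e.name == h.element).pattern)
            j = h.offset + int(rng.integers(0, w))
            seq[j] = _NUCS[int(rng.integers(0, 4))]
    return False


def gen_promoters(
    n: int,
    length: int = 2000,
    dictionary: Sequence[ElementDef] | None = None,
    prevalence: Mapping[str, float] | None = None,
    seed: int = 0,
    max_tries: int = 50,
) -> tuple[list[PromoterSeq], dict]:
    """Promoters of element-free background with elements planted per prevalence.

    Truth records every planted occurrence (element, strand, offset), and
    the construction guarantees the scanner's hit set equals the truth
    exactly.  Elements chosen for planting must therefore not contain one
    another's patterns (a realization of one would be an occurrence of the
    other); such a request exhausts the retry budget and raises.
    """
    dictionary = default_elements() if dictionary is None else list(dictionary)
    prevalence = dict(prevalence or {})
    known = {el.name for el in dictionary}
    unknown = set(prevalence) - known
    if unknown:
        raise ValueError(f"prevalence given for unknown elements: {sorted(unknown)}")
    for el in dictionary:
        if len(el.pattern) > length:
            raise ValueError(f"pattern {el.name} longer than promoter")
    if any(not 0 <= p <= 1 for p in prevalence.values()):
        raise ValueError("prevalences must lie in [0, 1]")
    rng = child_rng(seed, "promoters")
    by_name = {el.name: el for el in dictionary}
    promoters: list[PromoterSeq] = []
    truth: dict = {"seed": seed, "promoters": {}}
    for i in range(n):
        pid = f"prom{i + 1:04d}"
        # decide plantings first so rejection retries cannot bias prevalence
        wanted = [el for el in prevalence if rng.random() < prevalence[el]]
        for _ in range(max_tries):
            seq = [
                _NUCS[k] for k in rng.integers(0, 4, size=length)
            ]
            if not _scrub_background(rng, seq, dictionary):
                continue
            planted = []
            windows: list[tuple[int, int]] = []
            ok = True
            for el_name in wanted:
                el = by_name[el_name]
                w = len(el.pattern)
                for _ in range(200):
                    off = int(rng.integers(0, length - w + 1))
                    if all(off + w <= a or off >= b for a, b in windows):
                        break
                else:
                    ok = False
                    break
                strand = "+" if rng.random() < 0.5 else "-"
                real = _realize_pattern(rng, el.pattern)
                ins = real if strand == "+" else str(_Seq(real).reverse_complement())
                seq[off : off + w] = list(ins)
                windows.append((off, off + w))
                planted.append({"element": el_name, "strand": strand, "offset": off})
            if not ok:
                continue
            text = "".join(seq)
            found = {
                (h.element, h.strand, h.offset)
                for h in scan_elements(text, dictionary)
            }
            if found != {(p["element"], p["strand"], p["offset"]) for p in planted}:
                continue  # junction artifact or pattern containment: resample
            promoters.append(PromoterSeq(pid, text))
            truth["promoters"][pid] = planted
            break
        else:
            raise RuntimeError(f"could not generate promoter {pid} in {max_tries} tries")
    return promoters, truth


# ---------------------------------------------------------------------------
# expression matrices with planted DEG structure
# ---------------------------------------------------------------------------


def gen_expression(
    genes: int | Sequence[str],
    timepoints: Sequence[str] = ("T1", "T2", "T3", "T4"),
    deg_fraction: float = 0.2,
    effect_log2: float = 3.0,
    noise_sigma: float = 0.2,
    seed: int = 0,
    n_multi_period: int | None = None,
    min_multi_periods: int = 3,
    genotypes: Sequence[str] = ("M4", "101.14"),
) -> tuple[ExpressionMatrix, dict]:
    """Expression table with planted per-timepoint fold-change structure.

    Planted DEG cells get WS = WW * 2^(+-effect_log2) exactly; all other
    cells get multiplicative lognormal noise WS = WW * 2^N(0, noise_sigma).
    ``n_multi_period`` genes (default min(8, planted DEGs)) are differential
    in at least ``min_multi_periods`` timepoints; remaining planted DEGs are
    differential in fewer.
    """
    if effect_log2 <= 1:
        raise ValueError("effect_log2 must exceed 1 for unambiguous truth")
    if isinstance(genes, int):
        gene_ids = [f"gene{i + 1:04d}" for i in range(genes)]
    else:
        gene_ids = list(genes)
    rng = child_rng(seed, "expression")
    n = len(gene_ids)
    n_deg = int(round(deg_fraction * n))
    if n_multi_period is None:
        n_multi_period = min(8, n_deg)
    if n_multi_period > n_deg:
        raise ValueError("n_multi_period cannot exceed the number of planted DEGs")
    ntp = len(timepoints)
    rows = []
    truth: dict = {"seed": seed, "genotypes": {}}
    for genotype in genotypes:
        deg_genes = list(rng.choice(gene_ids, size=n_deg, replace=False))
        patterns: dict[str, dict[str, int]] = {g: {tp: 0 for tp in timepoints} for g in gene_ids}
        for gi, g in enumerate(deg_genes):
            if gi < n_multi_period:
                k = int(rng.integers(min_multi_periods, ntp + 1))
            else:
                k = int(rng.integers(1, min_multi_periods))
            tps = rng.choice(ntp, size=k, replace=False)
            for t in tps:
                patterns[g][timepoints[t]] = 1 if rng.random() < 0.5 else -1
        for g in gene_ids:
            for tp in timepoints:
                ww = float(rng.lognormal(mean=3.0, sigma=1.0))
                sign = patterns[g][tp]
                if sign:
                    ws = ww * 2.0 ** (sign * effect_log2)
                else:
                    ws = ww * 2.0 ** float(rng.normal(0.0, noise_sigma)) \
                        if noise_sigma > 0 else ww
                rows.append((g, genotype, "WW", tp, ww))
                rows.append((g, genotype, "WS", tp, ws))
        truth["genotypes"][genotype] = {
            "patterns": patterns,
            "deg_genes": sorted(deg_genes),
            "multi_period_genes": sorted(deg_genes[:n_multi_period]),
        }
    df = pd.DataFrame(rows, columns=["gene", "genotype", "condition", "timepoint", "value"])
    return ExpressionMatrix(df), truth


# ---------------------------------------------------------------------------
# gene models and genome
# ---------------------------------------------------------------------------


def gen_gff(
    n_genes: int,
    intron_count_distribution: Mapping[int, float] | Sequence[int] | None = None,
    seed: int = 0,
    n_chromosomes: int = 5,
    include_unanchored: bool = True,
    intergenic_gap: tuple[int, int] = (4500, 8000),
) -> tuple[str, dict[str, str], dict]:
    """A GFF3 document, its genome FASTA dict, and a per-gene truth table.

    Genes are laid out non-overlapping across chromosomes (plus an
    unanchored scaffold when requested); each gene's exon count is its drawn
    intron count + 1.  Intergenic gaps leave room for 2 kb promoters.
    """
    rng = child_rng(seed, "gff")
    if intron_count_distribution is None:
        intron_count_distribution = {0: 0.4, 1: 0.2, 2: 0.2, 3: 0.1, 5: 0.1}
    if isinstance(intron_count_distribution, Mapping):
        ks = sorted(intron_count_distribution)
        ps = np.array([intron_count_distribution[k] for k in ks], dtype=float)
        ps = ps / ps.sum()
        draw = lambda: int(rng.choice(ks, p=ps))
    else:
        pool = list(intron_count_distribution)
        draw = lambda: int(pool[int(rng.integers(0, len(pool)))])

    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    if include_unanchored:
        chroms.append("chrUn")
    cursors = {c: 0 for c in chroms}
    lines = ["##gff-version 3"]
    truth: dict = {"seed": seed, "genes": {}}
    records: list[tuple[str, str, int, int, str, list[tuple[int, int]]]] = []
    for i in range(n_genes):
        gid = f"g{i + 1:04d}"
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        n_introns = draw()
        start = cursors[chrom] + int(rng.integers(*intergenic_gap))
        exons = []
        pos = start
        for e in range(n_introns + 1):
            elen = int(rng.integers(120, 400))
            exons.append((pos, pos + elen - 1))
            pos += elen + int(rng.integers(60, 250))
        end = exons[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        cursors[chrom] = end
        records.append((gid, chrom, start, end, strand, exons))
        truth["genes"][gid] = {
            "chromosome": chrom, "start": start, "end": end,
            "strand": strand, "intron_count": n_introns,
        }
    # GFF must be grouped arbitrarily; emit in generation order
    for gid, chrom, start, end, strand, exons in records:
        lines.append(
            f"{chrom}\tringkit\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}"
        )
        tid = f"{gid}.t1"
        lines.append(
            f"{chrom}\tringkit\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={tid};Parent={gid}"
        )
        for k, (a, b) in enumerate(exons, start=1):
            lines.append(
                f"{chrom}\tringkit\texon\t{a}\t{b}\t.\t{strand}\t.\t"
                f"ID={tid}.exon{k};Parent={tid}"
            )
            lines.append(
                f"{chrom}\tringkit\tCDS\t{a}\t{b}\t.\t{strand}\t0\t"
                f"ID={tid}.cds{k};Parent={tid}"
            )
    genome = {
        c: "".join(_NUCS[k] for k in rng.integers(0, 4, size=cursors[c] + 3000))
        for c in chroms
    }
    return "\n".join(lines) + "\n", genome, truth


# ---------------------------------------------------------------------------
# coherent bundle for end-to-end runs
# ---------------------------------------------------------------------------


def write_bundle(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 24,
    n_domains: int = 18,
    n_dup_pairs: int = 3,
    omega: float = 0.3,
    target_ks: float = 0.3,
    cds_len_codons: int = 200,
    element_prevalence: Mapping[str, float] | None = None,
) -> dict:
    """Write a coherent synthetic study (FASTA/GFF3/TSV + truth.json).

    Gene models, genome, proteome, CDS set (with evolved paralog pairs),
    promoter elements planted into the genome upstream of each gene, and an
    expression matrix all share gene identifiers, so the full pipeline can
    run end-to-end against recorded truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = child_rng(seed, "bundle")

    gff_text, genome, gff_truth = gen_gff(n_genes, seed=seed)
    gene_ids = list(gff_truth["genes"])

    proteins, prot_truth = gen_proteome(
        n_proteins=n_genes, n_domains=n_domains, seed=seed
    )
    # rename proteins to gene ids (generation order)
    id_map = {p.id: g for p, g in zip(proteins, gene_ids)}
    proteins = [ProteinRecord(id_map[p.id], p.sequence, p.description) for p in proteins]
    prot_truth["proteins"] = {
        id_map[k]: v for k, v in prot_truth["proteins"].items()
    }

    # CDS: evolved pairs for the first 2*n_dup_pairs genes, random elsewhere
    cds: dict[str, str] = {}
    pair_truth = []
    for k in range(n_dup_pairs):
        a, b, t = evolve_cds_pair(
            cds_len_codons, omega=omega, target_ks=target_ks, seed=seed * 1000 + k
        )
        ga, gb = gene_ids[2 * k], gene_ids[2 * k + 1]
        cds[ga], cds[gb] = a, b
        pair_truth.append({"gene_a": ga, "gene_b": gb, **t})
    for g in gene_ids[2 * n_dup_pairs :]:
        cds[g] = _random_cds(rng, cds_len_codons)

    # plant elements into each gene's upstream window
    element_prevalence = dict(
        element_prevalence or {"ARE": 0.8, "MBS": 0.5, "LTR": 0.3}
    )
    dictionary = default_elements()
    proms, prom_truth = gen_promoters(
        n=n_genes, length=2000, dictionary=dictionary,
        prevalence=element_prevalence, seed=seed,
    )
    from .annotation import load_gene_models
    from .promoters import extract_promoter

    models = load_gene_models(gff_text)
    by_id = {m.gene_id: m for m in models}
    genome = dict(genome)
    prom_by_gene = {}
    for g, prom in zip(gene_ids, proms):
        m = by_id[g]
        contig = genome[m.chromosome]
        if m.strand == "-":
            lo, hi = m.end, m.end + 2000
            ins = str(_Seq(prom.sequence).reverse_complement())
        else:
            hi = m.start - 1
            lo = hi - 2000
            ins = prom.sequence
        genome[m.chromosome] = contig[:lo] + ins + contig[hi:]
        prom_by_gene[g] = prom_truth["promoters"][prom.gene_id]
        check = extract_promoter(m, genome, 2000)
        assert check.sequence == prom.sequence

    expr, expr_truth = gen_expression(gene_ids, seed=seed)

    # ---- write files
    with open(outdir / "proteome.faa", "w") as f:
        for p in proteins:
            f.write(f">{p.id} {p.description}\n{p.sequence}\n")
    with open(outdir / "cds.fna", "w") as f:
        for g in gene_ids:
            f.write(f">{g}\n{cds[g]}\n")
    with open(outdir / "genome.fa", "w") as f:
        for c in sorted(genome):
            f.write(f">{c}\n{genome[c]}\n")
    (outdir / "models.gff3").write_text(gff_text)
    expr.data.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    truth = {
        "seed": seed,
        "gff": gff_truth,
        "proteome": prot_truth,
        "dup_pairs": pair_truth,
        "promoter_elements": prom_by_gene,
        "expression": expr_truth,
        "element_prevalence": element_prevalence,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth
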