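"""Paralog detection, duplication classification, and NG86 Ka/Ks estimation.

The estimator is Nei-Gojobori (1986) counting: synonymous and nonsynonymous
sites are counted per codon as the fraction of single-nucleotide changes that
are synonymous (changes to stop codons are excluded and the fraction
renormalized, so S + N = 3 x codon count); differences between codons that
differ at several positions are averaged over all substitution pathways,
skipping pathways that pass through a stop codon.  Proportions are corrected
for multiple hits with the one-parameter Jukes-Cantor formula
d = -(3/4) ln(1 - 4p/3); the correction saturates when 4p/3 >= 1, in which
case the estimate is flagged undefined rather than raised.

Ka/Ks < 1 indicates purifying selection on the pair, > 1 diversifying
selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from functools import lru_cache
from itertools import combinations, permutations
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .annotation import GeneModel

__all__ = [
    "AlignScoring",
    "DupPair",
    "KaKsResult",
    "global_align_stats",
    "pairwise_identity",
    "detect_duplicate_pairs",
    "classify_duplication",
    "build_codon_alignment",
    "ng86_kaks",
    "ng86_site_counts",
    "selection_summary",
    "CODON_TO_AA",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
_NUCS = "ACGT"


@dataclass(frozen=True)
class AlignScoring:
    """Scoring for global nucleotide alignment (affine gaps).

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.5


@dataclass(frozen=True)
class DupPair:
    gene_a: str
    gene_b: str
    identity: float  # percent over aligned (both non-gap) columns
    aligned_fraction: float  # percent of the shorter CDS in aligned columns
    dup_class: str | None = None  # 'tandem' | 'segmental'
    ka: float | None = None
    ks: float | None = None
    ratio: float | None = None


@dataclass(frozen=True)
class KaKsResult:
    ka: float | None
    ks: float | None
    ratio: float | None
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    ka_saturated: bool = False
    ks_saturated: bool = False


# ---------------------------------------------------------------------------
# global alignment with a fully specified tie-break
#
# Identity must be a well-defined function of the two sequences, not of an
# aligner's arbitrary choice among co-optimal tracebacks.  The DP below keeps,
# per cell and gap state, the lexicographic optimum of
# (score, matches, -aligned_columns): best score first, then the most matched
# columns, then the fewest aligned columns (which maximizes percent identity).
# ---------------------------------------------------------------------------

_NEG = float("-inf")

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@_njit(cache=False)
def _align_core(ea, eb, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = ea.shape[0], eb.shape[0]
    NEG = -1e30
    # three states x (score, matches, cols); cols stored positive, minimized
    sM = np.full((n + 1, m + 1), NEG)
    sX = np.full((n + 1, m + 1), NEG)
    sY = np.full((n + 1, m + 1), NEG)
    mM = np.zeros((n + 1, m + 1), np.int64)
    mX = np.zeros((n + 1, m + 1), np.int64)
    mY = np.zeros((n + 1, m + 1), np.int64)
    cM = np.zeros((n + 1, m + 1), np.int64)
    cX = np.zeros((n + 1, m + 1), np.int64)
    cY = np.zeros((n + 1, m + 1), np.int64)
    sM[0, 0] = 0.0
    for i in range(1, n + 1):
        g = gap_open if i == 1 else gap_extend
        prev_s, prev_m, prev_c = sM[i - 1, 0], mM[i - 1, 0], cM[i - 1, 0]
        if sX[i - 1, 0] > prev_s or (
            sX[i - 1, 0] == prev_s
            and (mX[i - 1, 0] > prev_m or (mX[i - 1, 0] == prev_m and cX[i - 1, 0] < prev_c))
        ):
            prev_s, prev_m, prev_c = sX[i - 1, 0], mX[i - 1, 0], cX[i - 1, 0]
        sX[i, 0] = prev_s + g
        mX[i, 0] = prev_m
        cX[i, 0] = prev_c
    for j in range(1, m + 1):
        g = gap_open if j == 1 else gap_extend
        prev_s, prev_m, prev_c = sM[0, j - 1], mM[0, j - 1], cM[0, j - 1]
        if sY[0, j - 1] > prev_s or (
            sY[0, j - 1] == prev_s
            and (mY[0, j - 1] > prev_m or (mY[0, j - 1] == prev_m and cY[0, j - 1] < prev_c))
        ):
            prev_s, prev_m, prev_c = sY[0, j - 1], mY[0, j - 1], cY[0, j - 1]
        sY[0, j] = prev_s + g
        mY[0, j] = prev_m
        cY[0, j] = prev_c
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            hit = ea[i - 1] == eb[j - 1] and ea[i - 1] >= 0
            sub = match if hit else mismatch
            # best of three predecessors at (i-1, j-1)
            bs, bm, bc = sM[i - 1, j - 1], mM[i - 1, j - 1], cM[i - 1, j - 1]
            if sX[i - 1, j - 1] > bs or (
                sX[i - 1, j - 1] == bs
                and (mX[i - 1, j - 1] > bm or (mX[i - 1, j - 1] == bm and cX[i - 1, j - 1] < bc))
            ):
                bs, bm, bc = sX[i - 1, j - 1], mX[i - 1, j - 1], cX[i - 1, j - 1]
            if sY[i - 1, j - 1] > bs or (
                sY[i - 1, j - 1] == bs
                and (mY[i - 1, j - 1] > bm or (mY[i - 1, j - 1] == bm and cY[i - 1, j - 1] < bc))
            ):
                bs, bm, bc = sY[i - 1, j - 1], mY[i - 1, j - 1], cY[i - 1, j - 1]
            sM[i, j] = bs + sub
            mM[i, j] = bm + (1 if hit else 0)
            cM[i, j] = bc + 1
            # X: gap in b, consume a[i-1]
            bs, bm, bc = sM[i - 1, j] + gap_open, mM[i - 1, j], cM[i - 1, j]
            if sX[i - 1, j] + gap_extend > bs or (
                sX[i - 1, j] + gap_extend == bs
                and (mX[i - 1, j] > bm or (mX[i - 1, j] == bm and cX[i - 1, j] < bc))
            ):
                bs, bm, bc = sX[i - 1, j] + gap_extend, mX[i - 1, j], cX[i - 1, j]
            if sY[i - 1, j] + gap_open > bs or (
                sY[i - 1, j] + gap_open == bs
                and (mY[i - 1, j] > bm or (mY[i - 1, j] == bm and cY[i - 1, j] < bc))
            ):
                bs, bm, bc = sY[i - 1, j] + gap_open, mY[i - 1, j], cY[i - 1, j]
            sX[i, j] = bs
            mX[i, j] = bm
            cX[i, j] = bc
            # Y: gap in a, consume b[j-1]
            bs, bm, bc = sM[i, j - 1] + gap_open, mM[i, j - 1], cM[i, j - 1]
            if sY[i, j - 1] + gap_extend > bs or (
                sY[i, j - 1] + gap_extend == bs
                and (mY[i, j - 1] > bm or (mY[i, j - 1] == bm and cY[i, j - 1] < bc))
            ):
                bs, bm, bc = sY[i, j - 1] + gap_extend, mY[i, j - 1], cY[i, j - 1]
            if sX[i, j - 1] + gap_open > bs or (
                sX[i, j - 1] + gap_open == bs
                and (mX[i, j - 1] > bm or (mX[i, j - 1] == bm and cX[i, j - 1] < bc))
            ):
                bs, bm, bc = sX[i, j - 1] + gap_open, mX[i, j - 1], cX[i, j - 1]
            sY[i, j] = bs
            mY[i, j] = bm
            cY[i, j] = bc
    bs, bm, bc = sM[n, m], mM[n, m], cM[n, m]
    if sX[n, m] > bs or (sX[n, m] == bs and (mX[n, m] > bm or (mX[n, m] == bm and cX[n, m] < bc))):
        bs, bm, bc = sX[n, m], mX[n, m], cX[n, m]
    if sY[n, m] > bs or (sY[n, m] == bs and (mY[n, m] > bm or (mY[n, m] == bm and cY[n, m] < bc))):
        bs, bm, bc = sY[n, m], mY[n, m], cY[n, m]
    return bs, bm, bc


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}


def global_align_stats(
    a: str, b: str, scoring: AlignScoring | None = None
) -> tuple[float, int, int]:
    """Optimal global affine-gap alignment of nucleotide sequences.

    Returns (score, matches, aligned_columns) under the documented
    lexicographic tie-break among co-optimal alignments.  'N' matches
    nothing.
    """
    sc = scoring or AlignScoring()
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("empty sequence")
    for seq, name in ((a, "first"), (b, "second")):
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{name} sequence: invalid characters {sorted(bad)}")
    if _HAVE_NUMBA:
        ea = np.array([_ENC[c] for c in a], dtype=np.int64)
        eb = np.array([_ENC[c] for c in b], dtype=np.int64)
        s, mch, cols = _align_core(
            ea, eb, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend
        )
        return float(s), int(mch), int(cols)
    return _global_align_stats_py(a, b, sc)


def _global_align_stats_py(a: str, b: str, sc: AlignScoring) -> tuple[float, int, int]:
    n, m = len(a), len(b)

    # value = (score, matches, -aligned_cols); three states M / X(gap in b) / Y
    def better(u, v):
        return u if u >= v else v

    M = [[(_NEG, 0, 0)] * (m + 1) for _ in range(n + 1)]
    X = [[(_NEG, 0, 0)] * (m + 1) for _ in range(n + 1)]
    Y = [[(_NEG, 0, 0)] * (m + 1) for _ in range(n + 1)]
    M[0][0] = (0.0, 0, 0)
    for i in range(1, n + 1):
        prev = better(M[i - 1][0], X[i - 1][0])
        X[i][0] = (
            prev[0] + (sc.gap_open if i == 1 else sc.gap_extend),
            prev[1],
            prev[2],
        )
    for j in range(1, m + 1):
        prev = better(M[0][j - 1], Y[0][j - 1])
        Y[0][j] = (
            prev[0] + (sc.gap_open if j == 1 else sc.gap_extend),
            prev[1],
            prev[2],
        )
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            hit = ai == b[j - 1] and ai != "N"
            sub = sc.match if hit else sc.mismatch
            best_prev = better(better(Mp[j - 1], Xp[j - 1]), Yp[j - 1])
            Mi[j] = (
                best_prev[0] + sub,
                best_prev[1] + (1 if hit else 0),
                best_prev[2] - 1,
            )
            # gap in b (consume a[i-1])
            cand = better(
                (Mp[j][0] + sc.gap_open, Mp[j][1], Mp[j][2]),
                (Xp[j][0] + sc.gap_extend, Xp[j][1], Xp[j][2]),
            )
            Xi[j] = better(cand, (Yp[j][0] + sc.gap_open, Yp[j][1], Yp[j][2]))
            # gap in a (consume b[j-1])
            cand = better(
                (Mi[j - 1][0] + sc.gap_open, Mi[j - 1][1], Mi[j - 1][2]),
                (Yi[j - 1][0] + sc.gap_extend, Yi[j - 1][1], Yi[j - 1][2]),
            )
            Yi[j] = better(cand, (Xi[j - 1][0] + sc.gap_open, Xi[j - 1][1], Xi[j - 1][2]))
    score, matches, neg_cols = better(better(M[n][m], X[n][m]), Y[n][m])
    return score, matches, -neg_cols


def pairwise_identity(
    cds_a: str, cds_b: str, scoring: AlignScoring | None = None
) -> tuple[float, float]:
    """Percent identity and aligned fraction from a global alignment.

    identity = matches / aligned non-gap columns x 100;
    aligned_fraction = aligned columns / len(shorter sequence) x 100.
    """
    _, matches, cols = global_align_stats(cds_a, cds_b, scoring)
    identity = 100.0 * matches / cols if cols else 0.0
    aligned_fraction = 100.0 * cols / min(len(cds_a), len(cds_b))
    return identity, aligned_fraction


def detect_duplicate_pairs(
    models: Sequence[GeneModel],
    cds_map: Mapping[str, str],
    identity_threshold: float = 75.0,
    aligned_fraction_threshold: float = 75.0,
    scoring: AlignScoring | None = None,
) -> list[DupPair]:
    """All unordered gene pairs whose CDS exceed both similarity thresholds."""
    import logging

    usable = []
    for m in models:
        if m.gene_id in cds_map:
            usable.append(m)
        else:
            logging.getLogger(__name__).warning(
                "gene %s has no CDS; skipped from duplicate detection", m.gene_id
            )
    pairs: list[DupPair] = []
    for ma, mb in combinations(usable, 2):
        ident, frac = pairwise_identity(cds_map[ma.gene_id], cds_map[mb.gene_id], scoring)
        if ident > identity_threshold and frac > aligned_fraction_threshold:
            pairs.append(DupPair(ma.gene_id, mb.gene_id, ident, frac))
    return pairs


def classify_duplication(
    pair: DupPair,
    models: Sequence[GeneModel],
    max_gap_genes: int = 5,
    max_gap_bp: int = 100_000,
) -> str:
    """'tandem' if the genes sit close on one chromosome, else 'segmental'.

    Tandem requires the same chromosome, at most ``max_gap_genes`` other
    family members between the two genes, and a gap of at most ``max_gap_bp``
    between their nearest ends.
    """
    by_id = {m.gene_id: m for m in models}
    ma, mb = by_id[pair.gene_a], by_id[pair.gene_b]
    if ma.chromosome != mb.chromosome:
        return "segmental"
    lo, hi = sorted([ma, mb], key=lambda m: m.start)
    gap_bp = max(0, hi.start - lo.end)
    intervening = sum(
        1
        for m in models
        if m.chromosome == ma.chromosome
        and m.gene_id not in (ma.gene_id, mb.gene_id)
        and lo.start < m.start < hi.start
    )
    if intervening <= max_gap_genes and gap_bp <= max_gap_bp:
        return "tandem"
    return "segmental"


# ---------------------------------------------------------------------------
# codon alignment (protein-guided)
# ---------------------------------------------------------------------------


def _check_cds(cds: str, name: str) -> str:
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"{name}: CDS length {len(cds)} not divisible by 3")
    aa = str(Seq(cds).translate())
    core = aa[:-1] if aa.endswith("*") else aa
    if "*" in core:
        raise ValueError(f"{name}: internal stop codon at codon {core.index('*') + 1}")
    return cds


def build_codon_alignment(
    cds_a: str, cds_b: str, nucleotide: bool = False
) -> tuple[str, str]:
    """Gap-aligned CDS pair with intact codon columns.

    Default route: translate both CDS, align the proteins globally
    (BLOSUM62, gap open -10, extend -0.5) and back-thread codons through the
    protein alignment.  ``nucleotide=True`` instead aligns the CDS directly
    and is only suitable for gap-free high-identity pairs.
    """
    cds_a = _check_cds(cds_a, "sequence a")
    cds_b = _check_cds(cds_b, "sequence b")
    # drop terminal stop codons before aligning
    for_stop = lambda s: s[:-3] if CODON_TO_AA.get(s[-3:]) == "*" else s
    cds_a, cds_b = for_stop(cds_a), for_stop(cds_b)
    if nucleotide:
        if len(cds_a) != len(cds_b):
            raise ValueError("direct nucleotide mode requires equal-length CDS")
        return cds_a, cds_b
    prot_a = str(Seq(cds_a).translate())
    prot_b = str(Seq(cds_b).translate())
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(prot_a, prot_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _codon_syn_sites(codon: str) -> float:
    """Synonymous sites in one codon (stop-excluded renormalization)."""
    aa = CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if CODON_TO_AA[alt] == "*":
                continue
            valid += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


@lru_cache(maxsize=None)
def _codon_pair_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, pathway-averaged.

    Pathways through stop codons are excluded; if every pathway is blocked
    the average falls back to all pathways.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    blocked_paths = []
    for order in permutations(diff_pos):
        cur = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if CODON_TO_AA[nxt] == "*":
                blocked = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked_paths if blocked else paths).append((sd, nd))
    use = paths or blocked_paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _jc_correct(p: float) -> tuple[float | None, bool]:
    if p == 0.0:
        return 0.0, False
    if p * 4.0 / 3.0 >= 1.0:
        return None, True
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def ng86_site_counts(alignment: tuple[str, str]) -> tuple[float, float, float, float]:
    """(S sites, N sites, Sd, Nd) over gap-free aligned codon columns."""
    aln_a, aln_b = alignment
    if len(aln_a) != len(aln_b) or len(aln_a) % 3:
        raise ValueError("alignment rows must have equal codon-multiple length")
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    for k in range(0, len(aln_a), 3):
        ca, cb = aln_a[k : k + 3], aln_b[k : k + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if CODON_TO_AA[ca] == "*" or CODON_TO_AA[cb] == "*":
            raise ValueError(f"internal stop codon at aligned codon {k // 3 + 1}")
        s_a, s_b = _codon_syn_sites(ca), _codon_syn_sites(cb)
        s_sites += 0.5 * (s_a + s_b)
        n_sites += 3.0 - 0.5 * (s_a + s_b)
        sd, nd = _codon_pair_diffs(ca, cb)
        s_diffs += sd
        n_diffs += nd
    return s_sites, n_sites, s_diffs, n_diffs


def ng86_kaks(alignment: tuple[str, str]) -> KaKsResult:
    """NG86 Ka, Ks and their ratio from a codon alignment.

    The ratio is undefined (None) when Ks is zero or either Jukes-Cantor
    correction saturates.
    """
    s_sites, n_sites, s_diffs, n_diffs = ng86_site_counts(alignment)
    if s_sites == 0.0 or n_sites == 0.0:
        return KaKsResult(None, None, None, s_sites, n_sites, s_diffs, n_diffs)
    ks, ks_sat = _jc_correct(s_diffs / s_sites)
    ka, ka_sat = _jc_correct(n_diffs / n_sites)
    ratio = None
    if ka is not None and ks is not None and ks > 0.0:
        ratio = ka / ks
    return KaKsResult(
        ka=ka, ks=ks, ratio=ratio,
        s_sites=s_sites, n_sites=n_sites, s_diffs=s_diffs, n_diffs=n_diffs,
        ka_saturated=ka_sat, ks_saturated=ks_sat,
    )


def annotate_kaks(pair: DupPair, cds_map: Mapping[str, str]) -> DupPair:
    """Attach NG86 Ka/Ks estimates to a detected pair."""
    aln = build_codon_alignment(cds_map[pair.gene_a], cds_map[pair.gene_b])
    res = ng86_kaks(aln)
    return replace(pair, ka=res.ka, ks=res.ks, ratio=res.ratio)


@dataclass
class SelectionSummary:
    n_pairs: int
    class_counts: dict
    ratios: list
    n_below_half: int
    mean_ratio_below_half: float | None


def selection_summary(pairs: Sequence[DupPair], cutoff: float = 0.5) -> SelectionSummary:
    """Counts by duplication class and the mean Ka/Ks of pairs below cutoff.

    The mean over sub-cutoff ratios is rounded to 3 decimals; pairs with an
    undefined ratio are excluded from ratio statistics.
    """
    from collections import Counter

    class_counts = dict(Counter(p.dup_class for p in pairs if p.dup_class))
    ratios = [p.ratio for p in pairs if p.ratio is not None]
    below = [r for r in ratios if r < cutoff]
    mean_below = round(sum(below) / len(below), 3) if below else None
    return SelectionSummary(
        n_pairs=len(pairs),
        class_counts=class_counts,
        ratios=ratios,
        n_below_half=len(below),
        mean_ratio_below_half=mean_below,
    )
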