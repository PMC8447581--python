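"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package: the scanner oracle is a
plain recursive enumeration with its own overlap selection, the alignment
oracle enumerates alignments move by move, and the motif oracle checks
IUPAC sets position by position.
"""

from itertools import product

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# --- RING scanner oracle ---------------------------------------------------

_LIGANDS = "CCCHHCCC"


def oracle_assignments(seq: str, gaps) -> list[tuple]:
    """All valid 8-tuples, by recursive enumeration over ligand positions."""
    seq = seq.upper()
    out = []

    def rec(path):
        k = len(path)
        if k == 8:
            out.append(tuple(path))
            return
        lo, hi = gaps[k - 1]
        for pos in range(path[-1] + lo + 1, path[-1] + hi + 2):
            if pos < len(seq) and seq[pos] == _LIGANDS[k]:
                rec(path + [pos])

    for p1 in range(len(seq)):
        if seq[p1] == "C":
            rec([p1])
    return out


def oracle_assignments_naive(seq: str, gaps) -> list[tuple]:
    """Fully naive product enumeration (small sequences only)."""
    seq = seq.upper()
    pools = [
        [i for i, a in enumerate(seq) if a == lig] for lig in _LIGANDS
    ]
    out = []
    for tup in product(*pools):
        ok = all(
            gaps[k][0] <= tup[k + 1] - tup[k] - 1 <= gaps[k][1] for k in range(7)
        )
        if ok and all(tup[k] < tup[k + 1] for k in range(7)):
            out.append(tup)
    return sorted(out)


def oracle_select(assignments) -> list[tuple]:
    """Greedy non-overlap selection: leftmost p1, smallest span, smallest tuple."""
    chosen = []
    for pos in sorted(assignments, key=lambda p: (p[0], p[-1] - p[0], p)):
        if all(pos[-1] < c[0] or pos[0] > c[-1] for c in chosen):
            chosen.append(pos)
    return chosen


# --- global alignment oracle ----------------------------------------------


def oracle_align(a: str, b: str, match, mismatch, gap_open, gap_extend):
    """Best (score, matches, -cols) over every global alignment, by
    exhaustive enumeration of move sequences.  Exponential: tiny inputs only.
    """
    best = [None]

    def rec(i, j, prev, score, matches, cols):
        if i == len(a) and j == len(b):
            key = (score, matches, -cols)
            if best[0] is None or key > best[0]:
                best[0] = key
            return
        if i < len(a) and j < len(b):
            hit = a[i] == b[j] and a[i] != "N"
            rec(i + 1, j + 1, "M", score + (match if hit else mismatch),
                matches + (1 if hit else 0), cols + 1)
        if i < len(a):
            g = gap_extend if prev == "X" else gap_open
            rec(i + 1, j, "X", score + g, matches, cols)
        if j < len(b):
            g = gap_extend if prev == "Y" else gap_open
            rec(i, j + 1, "Y", score + g, matches, cols)

    rec(0, 0, "", 0.0, 0, 0)
    score, matches, neg = best[0]
    return score, matches, -neg


# --- promoter motif oracle -------------------------------------------------


def oracle_motif_hits(seq: str, elements) -> set[tuple]:
    """{(element, strand, offset)} by per-position IUPAC checking."""
    seq = seq.upper()
    hits = set()
    for el in elements:
        m = len(el.pattern)
        for i in range(len(seq) - m + 1):
            window = seq[i : i + m]
            if all(c in IUPAC_SETS[p] for c, p in zip(window, el.pattern)):
                hits.add((el.name, "+", i))
            if all(
                c in IUPAC_SETS[p] for c, p in zip(revcomp(window), el.pattern)
            ):
                hits.add((el.name, "-", i))
    return hits
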