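"""C3H2C3-type RING domain identification by the eight-metal-ligand pattern.

The RING cross-brace of this subfamily chelates two zinc ions through eight
conserved metal ligands (ml1..ml8) in the order Cys, Cys, Cys, His, His, Cys,
Cys, Cys.  Adjacent ligands are separated by spacers of variable length; the
family consensus is

    C-x2-C-x(9-39)-C-x(1-3)-H-x(2-3)-H-x2-C-x(4-48)-C-x2-C

The scanner enumerates every ligand assignment compatible with a set of
spacer bounds and reduces overlapping assignments to a set of non-overlapping
hits by a deterministic greedy rule (leftmost first ligand, then smallest
span, then lexicographically smallest position tuple).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "SpacerBounds",
    "RingDomainHit",
    "SpacerCensus",
    "scan_c3h2c3",
    "enumerate_assignments",
    "spacer_census",
    "position_bias",
    "domain_length_distribution",
    "expected_random_assignments",
]

#: the 20 standard residues; 'X' is tolerated as an unknown residue
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED = set(AMINO_ACIDS) | {"X"}

#: required residue at each of the eight metal-ligand positions
LIGAND_RESIDUES = ("C", "C", "C", "H", "H", "C", "C", "C")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifier; sequence is case-normalized."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        for i, aa in enumerate(seq):
            if aa not in _ALLOWED:
                raise ValueError(
                    f"{self.id}: invalid residue {aa!r} at position {i + 1}"
                )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SpacerBounds:
    """(min, max) residue counts for the seven gaps between adjacent ligands.

    Defaults follow the family consensus.
    """

    gaps: tuple[tuple[int, int], ...] = (
        (2, 2),
        (9, 39),
        (1, 3),
        (2, 3),
        (2, 2),
        (4, 48),
        (2, 2),
    )

    def __post_init__(self) -> None:
        if len(self.gaps) != 7:
            raise ValueError("exactly seven spacer bounds required")
        for i, (lo, hi) in enumerate(self.gaps):
            if not (0 <= lo <= hi):
                raise ValueError(f"gap g{i + 1}: need 0 <= min <= max, got ({lo}, {hi})")
        object.__setattr__(self, "gaps", tuple((int(a), int(b)) for a, b in self.gaps))

    @property
    def min_span(self) -> int:
        return 8 + sum(lo for lo, _ in self.gaps)

    @property
    def max_span(self) -> int:
        return 8 + sum(hi for _, hi in self.gaps)

    @classmethod
    def from_dict(cls, d: dict) -> "SpacerBounds":
        """Build from a mapping {'g1': [2, 2], ...} as read from YAML."""
        gaps = tuple(tuple(d[f"g{i}"]) for i in range(1, 8))
        return cls(gaps)


@dataclass(frozen=True)
class RingDomainHit:
    """One matched C3H2C3 domain (0-based ligand positions)."""

    protein_id: str
    positions: tuple[int, int, int, int, int, int, int, int]
    ligand_residues: tuple[str, ...] = LIGAND_RESIDUES

    @property
    def spacers(self) -> tuple[int, ...]:
        p = self.positions
        return tuple(p[i + 1] - p[i] - 1 for i in range(7))

    @property
    def span(self) -> int:
        return self.positions[-1] - self.positions[0] + 1


def _ligand_index(sequence: str) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {"C": [], "H": []}
    for i, aa in enumerate(sequence):
        if aa in idx:
            idx[aa].append(i)
    return idx


def enumerate_assignments(
    protein: ProteinRecord, bounds: SpacerBounds | None = None
) -> list[tuple[int, ...]]:
    """All ordered 8-tuples of positions satisfying residue and spacer rules.

    This is the raw assignment set before overlap resolution; it is also the
    quantity whose expectation on random background is analytically tractable.
    """
    bounds = bounds or SpacerBounds()
    seq = protein.sequence
    out: list[tuple[int, ...]] = []

    def extend(partial: list[int], ligand: int) -> None:
        if ligand == 8:
            out.append(tuple(partial))
            return
        lo, hi = bounds.gaps[ligand - 1]
        prev = partial[-1]
        want = LIGAND_RESIDUES[ligand]
        for pos in range(prev + lo + 1, min(prev + hi + 1, len(seq) - 1) + 1):
            if seq[pos] == want:
                partial.append(pos)
                extend(partial, ligand + 1)
                partial.pop()

    for p1, aa in enumerate(seq):
        if aa == "C":
            extend([p1], 1)
    return out


def _select_nonoverlapping(
    assignments: Sequence[tuple[int, ...]],
) -> tuple[list[tuple[int, ...]], list[tuple[int, ...]]]:
    """Greedy: leftmost p1, then smallest span, then smallest tuple."""
    ordered = sorted(assignments, key=lambda p: (p[0], p[-1] - p[0], p))
    chosen: list[tuple[int, ...]] = []
    alternates: list[tuple[int, ...]] = []
    for pos in ordered:
        if any(pos[0] <= c[-1] and c[0] <= pos[-1] for c in chosen):
            alternates.append(pos)
        else:
            chosen.append(pos)
    return chosen, alternates


def scan_c3h2c3(
    protein: ProteinRecord,
    bounds: SpacerBounds | None = None,
    return_alternates: bool = False,
):
    """Scan one protein for C3H2C3 RING domains.

    Returns the non-overlapping hit list; with ``return_alternates=True``
    also returns the valid assignments discarded by overlap resolution.
    """
    bounds = bounds or SpacerBounds()
    assignments = enumerate_assignments(protein, bounds)
    chosen, alternates = _select_nonoverlapping(assignments)
    hits = [RingDomainHit(protein.id, pos) for pos in chosen]
    if return_alternates:
        return hits, [RingDomainHit(protein.id, pos) for pos in alternates]
    return hits


@dataclass
class SpacerCensus:
    """Per-gap min/max and histograms over a hit collection, plus spans."""

    gap_min: tuple[int, ...]
    gap_max: tuple[int, ...]
    gap_histograms: tuple[Counter, ...]
    spans: list[int] = field(default_factory=list)

    @property
    def n_hits(self) -> int:
        return len(self.spans)


def spacer_census(hits: Sequence[RingDomainHit]) -> SpacerCensus:
    """Summarize spacer-length variation across hits (ml-to-ml distances)."""
    if not hits:
        raise ValueError("empty hit list: no census can be computed")
    histograms = tuple(Counter() for _ in range(7))
    for h in hits:
        for g, s in enumerate(h.spacers):
            histograms[g][s] += 1
    gap_min = tuple(min(c) for c in histograms)
    gap_max = tuple(max(c) for c in histograms)
    return SpacerCensus(gap_min, gap_max, histograms, [h.span for h in hits])


def position_bias(
    hits: Sequence[RingDomainHit],
    proteins: dict[str, ProteinRecord] | Iterable[ProteinRecord],
    flank: int = 4,
) -> dict[tuple[int, int], dict[str, float]]:
    """Residue frequencies at offsets around each metal ligand.

    Returns {(ligand_index 1..8, offset): {residue: frequency}} for offsets
    in [-flank, +flank] excluding 0.  Offsets falling outside the protein are
    excluded from the denominator.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if not isinstance(proteins, dict):
        proteins = {p.id: p for p in proteins}
    counts: dict[tuple[int, int], Counter] = {}
    for h in hits:
        seq = proteins[h.protein_id].sequence
        for li, pos in enumerate(h.positions, start=1):
            for off in range(-flank, flank + 1):
                if off == 0:
                    continue
                j = pos + off
                if 0 <= j < len(seq):
                    counts.setdefault((li, off), Counter())[seq[j]] += 1
    freqs: dict[tuple[int, int], dict[str, float]] = {}
    for key, ctr in counts.items():
        total = sum(ctr.values())
        freqs[key] = {aa: n / total for aa, n in ctr.items()}
    return freqs


def domain_length_distribution(
    hits: Sequence[RingDomainHit], span_set: Iterable[int] = (41, 42)
) -> tuple[Counter, float]:
    """Histogram of domain spans and percentage within ``span_set``.

    The percentage is rounded to one decimal, matching how family surveys
    report the dominant domain-length share.
    """
    if not hits:
        raise ValueError("empty hit list: no distribution can be computed")
    spans = Counter(h.span for h in hits)
    wanted = set(span_set)
    n_in = sum(n for s, n in spans.items() if s in wanted)
    pct = round(100.0 * n_in / sum(spans.values()), 1)
    return spans, pct


def expected_random_assignments(
    length: int,
    bounds: SpacerBounds | None = None,
    freqs: dict[str, float] | None = None,
) -> float:
    """Expected number of valid ligand assignments in an i.i.d. random sequence.

    Under an i.i.d. residue model each candidate assignment succeeds with
    probability fC^6 * fH^2; summing over all geometrically possible
    assignments gives the expectation used to bound the scanner's
    false-positive behaviour on domain-free background.
    """
    bounds = bounds or SpacerBounds()
    if freqs is None:
        freqs = {aa: 1.0 / 20 for aa in AMINO_ACIDS}
    p_assign = freqs.get("C", 0.0) ** 6 * freqs.get("H", 0.0) ** 2

    # count spacer tuples by total spacer sum via convolution of the 7 ranges
    totals: Counter = Counter({0: 1})
    for lo, hi in bounds.gaps:
        nxt: Counter = Counter()
        for tot, n in totals.items():
            for g in range(lo, hi + 1):
                nxt[tot + g] += n
        totals = nxt
    n_geom = 0
    for tot, n in totals.items():
        span = 8 + tot
        if span <= length:
            n_geom += n * (length - span + 1)
    return n_geom * p_assign
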