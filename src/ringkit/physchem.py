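"""Physicochemical descriptors of protein sequences: length, MW, pI.

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da), the convention of the common proteomics calculators.  The
isoelectric point is found by bisection on the Henderson-Hasselbalch net
charge, with a selectable pKa table (EMBOSS by default, Bjellqvist as the
alternative); published pI values computed with other tables typically agree
to within ~0.3 pH units.
"""

from __future__ import annotations

from dataclasses import dataclass

from .domain_scan import AMINO_ACIDS

__all__ = [
    "PKA_EMBOSS",
    "PKA_BJELLQVIST",
    "RESIDUE_MASSES",
    "WATER_MASS",
    "PhysChem",
    "molecular_weight",
    "net_charge_at_pH",
    "isoelectric_point",
    "physchem",
]

WATER_MASS = 18.0153

#: average (isotope-abundance weighted) residue masses, Da
RESIDUE_MASSES: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: mean residue mass used for unknown residue 'X' (configurable)
X_RESIDUE_MASS = 110.0

# pKa tables: termini plus ionizable side chains.
# sign +1 = group positive when protonated, -1 = negative when deprotonated.
PKA_EMBOSS: dict[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}

PKA_BJELLQVIST: dict[str, float] = {
    "Nterm": 7.5, "Cterm": 3.55,
    "C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98, "K": 10.0, "R": 12.0, "Y": 10.0,
}

_POSITIVE = ("Nterm", "H", "K", "R")
_NEGATIVE = ("Cterm", "C", "D", "E", "Y")


@dataclass(frozen=True)
class PhysChem:
    length: int
    molecular_weight: float  # Da
    pI: float

    @property
    def molecular_weight_kda(self) -> float:
        return round(self.molecular_weight / 1000.0, 2)


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    for i, aa in enumerate(seq):
        if aa not in RESIDUE_MASSES and aa != "X":
            raise ValueError(f"invalid residue {aa!r} at position {i + 1}")
    return seq


def molecular_weight(sequence: str, x_mass: float = X_RESIDUE_MASS) -> float:
    """Average molecular weight in Daltons (residue masses + one water)."""
    seq = _validate(sequence)
    return sum(RESIDUE_MASSES.get(aa, x_mass) for aa in seq) + WATER_MASS


def net_charge_at_pH(
    sequence: str, pH: float, pka_table: dict[str, float] | None = None
) -> float:
    """Henderson-Hasselbalch net charge at a given pH; decreasing in pH."""
    seq = _validate(sequence)
    pka = pka_table or PKA_EMBOSS
    counts = {g: seq.count(g) for g in set(AMINO_ACIDS) & set(pka)}
    counts["Nterm"] = counts["Cterm"] = 1
    charge = 0.0
    for group in _POSITIVE:
        n = counts.get(group, 0)
        if n and group in pka:
            charge += n / (1.0 + 10.0 ** (pH - pka[group]))
    for group in _NEGATIVE:
        n = counts.get(group, 0)
        if n and group in pka:
            charge -= n / (1.0 + 10.0 ** (pka[group] - pH))
    return charge


def isoelectric_point(
    sequence: str,
    pka_table: dict[str, float] | None = None,
    tol: float = 1e-3,
) -> float:
    """pH at which net charge crosses zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    c_lo = net_charge_at_pH(sequence, lo, pka_table)
    c_hi = net_charge_at_pH(sequence, hi, pka_table)
    if c_lo <= 0.0 or c_hi >= 0.0:
        raise ValueError("net charge does not cross zero within (0, 14)")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge_at_pH(sequence, mid, pka_table) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def physchem(sequence: str, pka_table: dict[str, float] | None = None) -> PhysChem:
    seq = _validate(sequence)
    return PhysChem(
        length=len(seq),
        molecular_weight=molecular_weight(seq),
        pI=isoelectric_point(seq, pka_table),
    )
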