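"""Peptide mass, net charge and isoelectric point.

Masses are *average* (isotope-abundance-weighted) residue masses as used
by ExPASy; a peptide's mass is the sum of its residue masses plus one
water (proteolysis leaves H at the N-terminus and OH at the C-terminus).

The charge model is compositional: each ionizable group (the two termini
and the C, D, E, H, K, R, Y side chains) contributes a rearranged
Henderson-Hasselbalch term at a given pH,

    positive groups:  +1 / (1 + 10**(pH - pKa))
    negative groups:  -1 / (1 + 10**(pKa - pH))

and the isoelectric point is the pH of zero net charge, located by
bisection on [0, 14] to 0.01 pH units.  Two built-in pKa sets are
provided: ``ipc_peptide`` (the peptide-calibrated IPC set, the default)
and ``typical`` (textbook values).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from .alphabet import AlphabetError, RESIDUES

#: Average residue masses, Da (ExPASy values; residue = amino acid - water).
AVERAGE_MASSES: Mapping[str, float] = MappingProxyType({
    "a": 71.0788,
    "c": 103.1388,
    "d": 115.0886,
    "e": 129.1155,
    "f": 147.1766,
    "g": 57.0519,
    "h": 137.1411,
    "i": 113.1594,
    "k": 128.1741,
    "l": 113.1594,
    "m": 131.1926,
    "n": 114.1038,
    "o": 237.3018,
    "p": 97.1167,
    "q": 128.1307,
    "r": 156.1875,
    "s": 87.0782,
    "t": 101.1051,
    "u": 150.0388,
    "v": 99.1326,
    "w": 186.2132,
    "y": 163.1760,
})

#: Average mass of one water molecule, Da.
WATER_MASS: float = 18.01528

N_TERM = "n_term"
C_TERM = "c_term"

#: Charge sign of each ionizable group.
CHARGE_SIGNS: Mapping[str, int] = MappingProxyType({
    N_TERM: +1, "h": +1, "k": +1, "r": +1,
    C_TERM: -1, "c": -1, "d": -1, "e": -1, "y": -1,
})


@dataclass(frozen=True)
class PkaSet:
    """A named table of pKa values for the nine ionizable groups."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self):
        missing = set(CHARGE_SIGNS) - set(self.values)
        if missing:
            raise ValueError(f"pKa set {self.name!r} missing groups: {missing}")


PKA_SETS: Mapping[str, PkaSet] = MappingProxyType({
    "ipc_peptide": PkaSet("ipc_peptide", MappingProxyType({
        N_TERM: 9.564,
        "c": 8.297,
        "d": 3.887,
        "e": 4.317,
        "h": 6.018,
        "k": 10.517,
        "r": 12.503,
        "y": 10.071,
        C_TERM: 2.383,
    })),
    "typical": PkaSet("typical", MappingProxyType({
        N_TERM: 8.0,
        "c": 8.3,
        "d": 4.1,
        "e": 4.1,
        "h": 6.0,
        "k": 10.8,
        "r": 12.5,
        "y": 10.9,
        C_TERM: 3.1,
    })),
})

DEFAULT_PKA_SET = "ipc_peptide"


def get_pka_set(name: str | PkaSet) -> PkaSet:
    if isinstance(name, PkaSet):
        return name
    try:
        return PKA_SETS[name]
    except KeyError:
        raise KeyError(
            f"unknown pKa set {name!r}; available: {', '.join(sorted(PKA_SETS))}"
        ) from None


def peptide_mass(sequence: str) -> float:
    """Average molecular mass of a peptide in Da (unrounded).

    Sum of residue masses plus one water.  Display formatting rounds to
    four decimals; the full-precision value is returned so that mass
    bookkeeping across a digestion stays exact.
    """
    if not sequence:
        raise ValueError("cannot compute the mass of an empty peptide")
    total = WATER_MASS
    for i, aa in enumerate(sequence.lower()):
        try:
            total += AVERAGE_MASSES[aa]
        except KeyError:
            raise AlphabetError(aa, i) from None
    return total


def net_charge(sequence: str, pH: float, pka_set: str | PkaSet = DEFAULT_PKA_SET) -> float:
    """Net charge of a peptide at a given pH.

    One N-terminal and one C-terminal term plus one term per ionizable
    side-chain occurrence; other residues contribute nothing.
    """
    if not sequence:
        raise ValueError("cannot compute the charge of an empty peptide")
    pka = get_pka_set(pka_set).values
    seq = sequence.lower()

    def term(group: str) -> float:
        if CHARGE_SIGNS[group] > 0:
            return 1.0 / (1.0 + 10.0 ** (pH - pka[group]))
        return -1.0 / (1.0 + 10.0 ** (pka[group] - pH))

    charge = term(N_TERM) + term(C_TERM)
    for i, aa in enumerate(seq):
        if aa in CHARGE_SIGNS:
            charge += term(aa)
        elif aa not in RESIDUES:
            raise AlphabetError(aa, i)
    return charge


def isoelectric_point(
    sequence: str, pka_set: str | PkaSet = DEFAULT_PKA_SET, accuracy: float = 0.01
) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    Starts from pH 7 and halves the bracket until it is narrower than
    *accuracy* (default 0.01).  Net charge is strictly decreasing in pH
    and every peptide carries both termini, so the root is unique.
    """
    lo, hi = 0.0, 14.0
    pka = get_pka_set(pka_set)
    while hi - lo > accuracy:
        mid = (lo + hi) / 2.0
        charge = net_charge(sequence, mid, pka)
        if charge < 0.0:
            hi = mid
        elif charge > 0.0:
            lo = mid
        else:
            return mid
    return (lo + hi) / 2.0
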