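"""Amine-group accounting for free amino acids, dipeptides and tripeptides.

The ninhydrin assay counts free (unbonded) amine groups.  Every peptide
carries at least the one backbone alpha-amine; residues with a second
ninhydrin-reactive amine on the side chain (glutamine, arginine and the
like — roughly 30 % of the standard alphabet) contribute one extra group
each.  Hydrolysing a peptide bond exposes one additional alpha-amine, so a
dipeptide gains one amine group on full hydrolysis and a tripeptide gains
two.  This module holds the residue conventions, the species classes
(``A``, ``x1``–``x3``, ``y1``–``y4``, indexed by intact amine-group count)
and the forward model mapping a composition to the pre-/post-hydrolysis
readings (F, T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "STANDARD_RESIDUES",
    "DEFAULT_TWO_AMINE_RESIDUES",
    "ResidueTable",
    "Composition",
    "AmineReadings",
    "count_amine_groups",
    "classify_peptide",
    "forward_readings",
    "enumerate_peptide_count",
]

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residues modelled as carrying a second ninhydrin-reactive amine group.
#: Chosen so that 6/20 = 30 % of the alphabet is two-amine, matching the
#: fraction observed for side-chain amines (Gln, Arg, Lys, Asn, His, Trp);
#: the set is a convention and is fully overridable via ResidueTable.
DEFAULT_TWO_AMINE_RESIDUES = frozenset("QRKNHW")


@dataclass(frozen=True)
class ResidueTable:
    """Alphabet of residues and the subset flagged as two-amine.

    Parameters
    ----------
    residues
        The residue alphabet (default: the 20 standard one-letter codes).
    two_amine_residues
        Residues contributing one extra ninhydrin-reactive amine group.
        Must be a subset of ``residues``.
    """

    residues: frozenset[str] = STANDARD_RESIDUES
    two_amine_residues: frozenset[str] = DEFAULT_TWO_AMINE_RESIDUES

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", frozenset(self.residues))
        object.__setattr__(
            self, "two_amine_residues", frozenset(self.two_amine_residues)
        )
        if not self.two_amine_residues <= self.residues:
            extra = sorted(self.two_amine_residues - self.residues)
            raise ValueError(
                f"two-amine residues not in the alphabet: {extra}"
            )

    @property
    def two_amine_fraction(self) -> float:
        """Fraction of the alphabet carrying a second amine group."""
        return len(self.two_amine_residues) / len(self.residues)


DEFAULT_TABLE = ResidueTable()

#: Species class labels indexed by (peptide length, amine-group count).
_CLASS_BY_LENGTH = {1: ("A",), 2: ("x1", "x2", "x3"), 3: ("y1", "y2", "y3", "y4")}


def count_amine_groups(sequence: str, table: ResidueTable = DEFAULT_TABLE) -> int:
    """Number of free amine groups the ninhydrin assay sees on an intact peptide.

    One backbone alpha-amine plus one per two-amine residue; a single
    glutamine therefore reads as 2 amine groups, the tripeptide ``QQQ``
    as 4.

    Raises
    ------
    ValueError
        If the sequence is empty, longer than 3 residues, or contains a
        residue code outside the table.
    """
    n = len(sequence)
    if not 1 <= n <= 3:
        raise ValueError(
            f"peptide length must be 1-3 residues, got {n} ({sequence!r})"
        )
    for ch in sequence:
        if ch not in table.residues:
            raise ValueError(f"unknown residue code {ch!r} in {sequence!r}")
    return 1 + sum(ch in table.two_amine_residues for ch in sequence)


def classify_peptide(sequence: str, table: ResidueTable = DEFAULT_TABLE) -> str:
    """Species class of a 1-3 residue peptide: ``A``, ``x1``-``x3`` or ``y1``-``y4``.

    The class index equals the intact amine-group count, so e.g. ``QQ``
    (3 amine groups) is class ``x3``.  Single residues are always class
    ``A``, whatever their amine count.
    """
    k = count_amine_groups(sequence, table)
    if len(sequence) == 1:
        return "A"
    return _CLASS_BY_LENGTH[len(sequence)][k - 1]


def enumerate_peptide_count(length: int, alphabet_size: int = 20) -> int:
    """Number of distinct peptide sequences of the given length.

    400 dipeptides and 8000 tripeptides for the standard alphabet.
    """
    if length not in (2, 3):
        raise ValueError(f"length must be 2 or 3, got {length}")
    return alphabet_size**length


@dataclass(frozen=True)
class Composition:
    """Class abundances in amine-group-equivalent concentration units.

    ``A`` is the free-amino-acid pool, counted with exactly one amine
    group each (the model assumption under which the balance equations
    close); ``x1``-``x3`` are dipeptide classes with 1-3 intact amine
    groups, ``y1``-``y4`` tripeptide classes with 1-4.  Abundances are
    non-negative reals — plasma concentrations, not molecule counts.
    """

    A: float = 0.0
    x1: float = 0.0
    x2: float = 0.0
    x3: float = 0.0
    y1: float = 0.0
    y2: float = 0.0
    y3: float = 0.0
    y4: float = 0.0

    def __post_init__(self) -> None:
        for name in ("A", "x1", "x2", "x3", "y1", "y2", "y3", "y4"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"composition field {name} must be >= 0, got {v}")

    @property
    def x(self) -> float:
        """Total dipeptide abundance."""
        return self.x1 + self.x2 + self.x3

    @property
    def y(self) -> float:
        """Total tripeptide abundance."""
        return self.y1 + self.y2 + self.y3 + self.y4


@dataclass(frozen=True)
class AmineReadings:
    """A paired ninhydrin measurement: F before hydrolysis, T after (µg/mL)."""

    F: float
    T: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.F) and math.isfinite(self.T)):
            raise ValueError(f"non-finite readings F={self.F}, T={self.T}")


def forward_readings(c: Composition) -> AmineReadings:
    """Map a composition to the (F, T) amine-group equivalents it produces.

    Before hydrolysis each class contributes its intact amine-group count:

        F = A + x1 + 2 x2 + 3 x3 + y1 + 2 y2 + 3 y3 + 4 y4

    Hydrolysis breaks every peptide bond, releasing one new alpha-amine per
    bond, so each dipeptide gains 1 group and each tripeptide gains 2:

        T = F + x + 2 y
    """
    F = (
        c.A
        + c.x1 + 2 * c.x2 + 3 * c.x3
        + c.y1 + 2 * c.y2 + 3 * c.y3 + 4 * c.y4
    )
    T = F + c.x + 2 * c.y
    return AmineReadings(F=F, T=T)
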