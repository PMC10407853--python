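"""Molecular-formula and crystallographic identity arithmetic.

Everything a characterization section prints from the formula alone:
average (Mr) and monoisotopic masses, elemental-analysis percentages,
electron counts and F(000), plus unit-cell volume and crystal density.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Mapping

from .periodic import PERIODIC_TABLE, UnknownElementError, element

__all__ = [
    "MolecularFormula",
    "CrystalCell",
    "parse_formula",
    "average_mass",
    "monoisotopic_mass",
    "elemental_percentages",
    "electron_count",
    "f000",
    "cell_volume",
    "crystal_density",
    "round_half_up",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Avogadro conversion: 1 u / A^3 = 1.66054 g/cm^3
_U_PER_A3_TO_G_PER_CM3 = 1.66054


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as journals print values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MolecularFormula:
    """An element -> count map, e.g. ``{"C": 39, "H": 35, ...}``."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            if sym not in PERIODIC_TABLE:
                raise UnknownElementError(f"unknown element symbol {sym!r}")
            if not isinstance(n, int) or n < 1:
                raise ValueError(f"count for {sym} must be a positive integer, got {n!r}")
        object.__setattr__(self, "counts", dict(self.counts))

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        syms = sorted(self.counts, key=lambda s: (s != "C", s != "H", s))
        return "".join(f"{s}{self.counts[s] if self.counts[s] > 1 else ''}" for s in syms)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C39H35ClN4O4"``.

    An absent count means 1; repeated symbols accumulate.  Raises
    ``ValueError`` on an empty string and :class:`UnknownElementError`
    naming the offending token on an unrecognized symbol.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise ValueError(f"cannot parse formula at {text[pos:]!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in PERIODIC_TABLE:
            raise UnknownElementError(f"unknown element symbol {sym!r} in {text!r}")
        pos = m.end()
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
    return MolecularFormula(counts)


def average_mass(f: MolecularFormula) -> float:
    """Relative molar mass Mr in u, from standard atomic weights."""
    return sum(n * element(s).weight for s, n in f.counts.items())


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass in u (most abundant isotope of each element)."""
    return sum(n * element(s).monoisotopic for s, n in f.counts.items())


def elemental_percentages(f: MolecularFormula) -> Dict[str, float]:
    """Mass percent of each element, as in an "anal. calcd" line.

    Percentages sum to 100 within floating-point error.
    """
    if not f.counts:
        raise ValueError("elemental percentages of the empty formula are undefined")
    total = average_mass(f)
    return {s: 100.0 * n * element(s).weight / total for s, n in f.counts.items()}


def electron_count(f: MolecularFormula) -> int:
    """Total electrons of the neutral molecule (sum of atomic numbers)."""
    return sum(n * element(s).number for s, n in f.counts.items())


def f000(f: MolecularFormula, Z: int) -> int:
    """F(000) as total electrons per unit cell: Z x electron count.

    Neutral-atom approximation without anomalous-dispersion terms,
    which is how the integer printed in crystal-data tables is defined.
    """
    if Z <= 0:
        raise ValueError(f"Z must be a positive integer, got {Z}")
    return Z * electron_count(f)


@dataclass(frozen=True)
class CrystalCell:
    """Unit-cell parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    Z: int = 1
    space_group: str = "P1"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {ang} out of (0, 180)")
        if self.Z < 1:
            raise ValueError("Z must be >= 1")

    @property
    def volume(self) -> float:
        return cell_volume(self)


def cell_volume(cell: CrystalCell) -> float:
    """Unit-cell volume in cubic Angstrom.

    General triclinic formula
    ``V = abc sqrt(1 - cos^2 a - cos^2 b - cos^2 g + 2 cos a cos b cos g)``;
    for a monoclinic cell this reduces to ``abc sin(beta)``.
    """
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if disc <= 0.0:
        raise ValueError("degenerate cell: angle combination gives non-positive volume")
    return cell.a * cell.b * cell.c * math.sqrt(disc)


def crystal_density(cell: CrystalCell, f: MolecularFormula) -> float:
    """Calculated density in g/cm^3: rho = Z Mr 1.66054 / V(A^3)."""
    return cell.Z * average_mass(f) * _U_PER_A3_TO_G_PER_CM3 / cell_volume(cell)
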