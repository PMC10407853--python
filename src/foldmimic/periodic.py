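"""Immutable per-element data used across the package.

Standard atomic weights follow the IUPAC 2021 conventional values;
monoisotopic masses are those of the most abundant isotope; van der
Waals radii are the Bondi set (with Mantina's extensions where Bondi
gives none), matching common Hirshfeld-surface practice; covalent
radii follow Cordero et al. and are used only for distance-based bond
perception on formats without a bond block.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType


@dataclass(frozen=True)
class ElementData:
    """Per-element constants.

    Attributes
    ----------
    number : int
        Atomic number (= electrons of the neutral atom).
    weight : float
        Standard atomic weight in u.
    monoisotopic : float
        Mass of the most abundant isotope in u.
    vdw_radius : float
        van der Waals radius in Angstrom.
    covalent_radius : float
        Single-bond covalent radius in Angstrom.
    """

    number: int
    weight: float
    monoisotopic: float
    vdw_radius: float
    covalent_radius: float


_ELEMENTS = {
    "H":  ElementData(1,  1.008,      1.00782503, 1.20, 0.31),
    "B":  ElementData(5,  10.81,      11.00930536, 1.92, 0.84),
    "C":  ElementData(6,  12.011,     12.0,        1.70, 0.76),
    "N":  ElementData(7,  14.007,     14.00307401, 1.55, 0.71),
    "O":  ElementData(8,  15.999,     15.99491462, 1.52, 0.66),
    "F":  ElementData(9,  18.99840316, 18.99840322, 1.47, 0.57),
    "Na": ElementData(11, 22.98976928, 22.98976928, 2.27, 1.66),
    "Mg": ElementData(12, 24.305,     23.98504170, 1.73, 1.41),
    "Si": ElementData(14, 28.085,     27.97692653, 2.10, 1.11),
    "P":  ElementData(15, 30.97376200, 30.97376163, 1.80, 1.07),
    "S":  ElementData(16, 32.06,      31.97207100, 1.80, 1.05),
    "Cl": ElementData(17, 35.45,      34.96885268, 1.75, 1.02),
    "K":  ElementData(19, 39.0983,    38.96370668, 2.75, 2.03),
    "Ca": ElementData(20, 40.078,     39.96259098, 2.31, 1.76),
    "Fe": ElementData(26, 55.845,     55.93493750, 2.05, 1.32),
    "Zn": ElementData(30, 65.38,      63.92914220, 2.10, 1.22),
    "Br": ElementData(35, 79.904,     78.91833710, 1.85, 1.20),
    "I":  ElementData(53, 126.90447,  126.90447300, 1.98, 1.39),
}

#: Read-only element table; symbols are case-sensitive ("Cl", not "CL").
PERIODIC_TABLE = MappingProxyType(_ELEMENTS)


class UnknownElementError(ValueError):
    """Raised when an element symbol is not in :data:`PERIODIC_TABLE`."""


def element(symbol: str) -> ElementData:
    """Look up an element by symbol, raising :class:`UnknownElementError`."""
    try:
        return PERIODIC_TABLE[symbol]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol {symbol!r}") from None


def vdw_radius(symbol: str) -> float:
    """van der Waals radius in Angstrom for *symbol*."""
    return element(symbol).vdw_radius
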