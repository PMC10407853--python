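"""Worked-example data for a hydantoin-based peptidomimetic.

Characterization inputs for one member of a hydantoin
universal-peptidomimetic series — a chlorophenyl/naphthylmethyl
derivative that crystallizes in C2 with a beta-turn fold — plus two
sibling formulas used in the README examples.  These are published
experimental identifiers (formula, unit cell, Hirshfeld surface
volume/area, CrystalExplorer contact composition); everything derived
from them (Mr, F(000), density, globularity, enrichment ratios) is
computed by the package.
"""

from .chemid import CrystalCell
from .xtalstats import ContactTable

#: chlorophenyl/naphthylmethyl hydantoin peptidomimetic (the crystallized one)
HYDANTOIN_FORMULA = "C39H35ClN4O4"

#: dicyclohexyl sibling compound (elemental-analysis example)
HYDANTOIN_FORMULA_DICYCLOHEXYL = "C36H42N4O4"

#: glycyl/benzhydryl sibling compound (ESI-MS example)
HYDANTOIN_FORMULA_GLYCYL = "C26H34N4O4"

#: monoclinic C2 cell of the crystallized compound, Z = 4
HYDANTOIN_CELL = CrystalCell(
    a=33.471, b=9.5152, c=10.877, alpha=90.0, beta=99.48, gamma=90.0,
    Z=4, space_group="C2",
)

#: Hirshfeld-surface volume (A^3) and area (A^2) from CrystalExplorer
HYDANTOIN_HS_VOLUME = 845.05
HYDANTOIN_HS_AREA = 641.95

#: Hirshfeld-surface composition: element surface fractions S_X (%) and
#: merged contact fractions C_XY (%), CrystalExplorer-style export
HYDANTOIN_CONTACT_TABLE = ContactTable(
    surface={"H": 72.2, "C": 15.2, "N": 0.5, "O": 7.8, "Cl": 4.4},
    contacts={
        ("H", "H"): 49.1,
        ("C", "H"): 24.7,
        ("C", "C"): 1.6,
        ("N", "H"): 0.3,
        ("C", "N"): 0.6,
        ("N", "N"): 0.0,
        ("O", "H"): 13.3,
        ("C", "O"): 1.0,
        ("N", "O"): 0.0,
        ("O", "O"): 0.6,
        ("Cl", "H"): 7.9,
        ("C", "Cl"): 0.9,
        ("Cl", "N"): 0.0,
        ("Cl", "O"): 0.0,
        ("Cl", "Cl"): 0.0,
    },
)

#: measured geometry of the two structure-defining H-bonds in the
#: crystal: the intramolecular (beta-turn-closing) and the chain-forming
#: intermolecular N-H...O contact
HYDANTOIN_HBOND_INTRA = {"d_da": 2.727, "d_ha": 1.965, "angle_dha": 147.2}
HYDANTOIN_HBOND_INTER = {"d_da": 2.843, "d_ha": 2.001, "angle_dha": 166.1}
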