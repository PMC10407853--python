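"""Crystal-packing and Hirshfeld-surface contact statistics.

The Hirshfeld surface itself (a promolecule electron-density
partition) is produced upstream by programs such as CrystalExplorer;
this module consumes its exports — surface composition tables,
(d_i, d_e) fingerprint points, surface volume and area — and computes
the derived statistics: random-contact expectations, contact
enrichment ratios E_XY = C_XY / R_XY with the R < 0.9 % masking rule,
globularity, d_norm, fingerprint histograms, and geometric H-bond
tables over symmetry-expanded crystal packings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .chemid import round_half_up
from .geomcore import HBondGeometry, hbond_geometry, hbond_ring_size
from .structio import CrystalStructure, ExpandedAtom, expand_symmetry

__all__ = [
    "ContactTable",
    "EnrichmentResult",
    "HirshfeldSummary",
    "FingerprintPoint",
    "HBondRecord",
    "random_contacts",
    "enrichment",
    "globularity",
    "dnorm",
    "fingerprint_hist",
    "hbond_table",
    "read_contact_table",
    "write_contact_table",
]

#: pairs with a random-contact expectation below this (%) have no
#: meaningful enrichment and are masked
MASK_THRESHOLD = 0.9

Pair = Tuple[str, str]


def _pair(x: str, y: str) -> Pair:
    """Canonical unordered pair key (reciprocal contacts are merged)."""
    return (x, y) if x <= y else (y, x)


@dataclass
class ContactTable:
    """Surface composition S_X (%) and merged contact fractions C_XY (%)."""

    surface: Dict[str, float]
    contacts: Dict[Pair, float]

    def __post_init__(self) -> None:
        self.contacts = {_pair(*k): v for k, v in self.contacts.items()}
        if any(v < 0 for v in self.surface.values()) or any(
            v < 0 for v in self.contacts.values()
        ):
            raise ValueError("fractions must be non-negative")
        for total, what in ((sum(self.surface.values()), "surface"),
                            (sum(self.contacts.values()), "contact")):
            if abs(total - 100.0) > 0.2:
                raise ValueError(f"{what} fractions sum to {total}, not 100 +/- 0.2")

    @property
    def elements(self) -> List[str]:
        return list(self.surface)


@dataclass
class EnrichmentResult:
    """Random contacts R_XY and enrichment ratios E_XY (None = masked)."""

    random: Dict[Pair, float]
    enrichment: Dict[Pair, Optional[float]]

    def rounded(self, ndigits: int = 1) -> Dict[Pair, Optional[float]]:
        return {
            k: (None if v is None else round_half_up(v, ndigits))
            for k, v in self.enrichment.items()
        }

    @property
    def enriched_pairs(self) -> List[Pair]:
        """Pairs whose ratio (at 1 d.p., as reported) reaches 1.0."""
        return [k for k, v in self.rounded().items() if v is not None and v >= 1.0]


@dataclass(frozen=True)
class HirshfeldSummary:
    """Volume (A^3), area (A^2) and globularity of one Hirshfeld surface."""

    volume: float
    area: float

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.area <= 0:
            raise ValueError("volume and area must be positive")

    @property
    def globularity(self) -> float:
        return globularity(self.volume, self.area)


@dataclass(frozen=True)
class FingerprintPoint:
    """One surface point: internal and external nearest-nucleus distances."""

    d_i: float
    d_e: float

    def __post_init__(self) -> None:
        if self.d_i <= 0 or self.d_e <= 0:
            raise ValueError("d_i and d_e must be positive")


def random_contacts(surface: Dict[str, float]) -> Dict[Pair, float]:
    """Random-contact expectations R_XY (%) from surface fractions S_X.

    With s_X = S_X/100: R_XX = s_X^2 * 100 and R_XY = 2 s_X s_Y * 100
    for X != Y (reciprocal contacts merged), so that the R values sum
    to (sum s)^2 * 100 ~ 100.
    """
    if any(v < 0 for v in surface.values()):
        raise ValueError("surface fractions must be non-negative")
    s = {k: v / 100.0 for k, v in surface.items()}
    out: Dict[Pair, float] = {}
    elems = list(s)
    for i, x in enumerate(elems):
        for y in elems[i:]:
            out[_pair(x, y)] = (s[x] ** 2 if x == y else 2.0 * s[x] * s[y]) * 100.0
    return out


def enrichment(table: ContactTable, mask_threshold: float = MASK_THRESHOLD) -> EnrichmentResult:
    """Contact enrichment E_XY = C_XY / R_XY.

    Pairs whose random expectation falls below *mask_threshold* (%)
    are masked (None): their observed fractions are too small for the
    ratio to be meaningful.  A pair with R = 0 but C > 0 is masked
    with a warning.
    """
    R = random_contacts(table.surface)
    E: Dict[Pair, Optional[float]] = {}
    for pair, r in R.items():
        c = table.contacts.get(pair, 0.0)
        if r == 0.0 and c > 0.0:
            warnings.warn(f"contact {pair} observed but impossible at random; masked")
            E[pair] = None
        elif r < mask_threshold:
            E[pair] = None
        else:
            E[pair] = c / r
    return EnrichmentResult(random=R, enrichment=E)


def globularity(volume: float, area: float) -> float:
    """G = (36 pi)^(1/3) V^(2/3) / A: sphere-equivalent over actual area.

    Equals 1 for a sphere and decreases as the surface grows more
    structured relative to its volume.
    """
    if volume <= 0 or area <= 0:
        raise ValueError("volume and area must be positive")
    return (36.0 * math.pi) ** (1.0 / 3.0) * volume ** (2.0 / 3.0) / area


def dnorm(point: FingerprintPoint, r_i_vdw: float, r_e_vdw: float) -> float:
    """Normalized contact distance of one surface point.

    d_norm = (d_i - r_i^vdW)/r_i^vdW + (d_e - r_e^vdW)/r_e^vdW;
    negative where the contact dips inside the van der Waals sum.
    """
    if r_i_vdw <= 0 or r_e_vdw <= 0:
        raise ValueError("van der Waals radii must be positive")
    return (point.d_i - r_i_vdw) / r_i_vdw + (point.d_e - r_e_vdw) / r_e_vdw


def fingerprint_hist(
    points: Sequence[FingerprintPoint],
    bin_width: float = 0.01,
    extent: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D histogram of (d_i, d_e) with half-open bins [lo, lo + w).

    Returns (counts, d_i edges, d_e edges) with d_i on the first axis.
    When *extent* is omitted the grid is sized to cover every point
    (so counts always sum to the number of points); with an explicit
    extent, points outside it are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if not points:
        return np.zeros((0, 0), dtype=int), np.array([]), np.array([])
    di = np.array([p.d_i for p in points])
    de = np.array([p.d_e for p in points])
    if extent is None:
        lo = bin_width * math.floor(min(di.min(), de.min()) / bin_width)
        hi = bin_width * (math.floor(max(di.max(), de.max()) / bin_width) + 1)
    else:
        lo, hi = extent
        keep = (di >= lo) & (di < hi) & (de >= lo) & (de < hi)
        di, de = di[keep], de[keep]
    nbins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(nbins + 1)
    ii = np.clip(np.floor((di - lo) / bin_width).astype(int), 0, nbins - 1)
    jj = np.clip(np.floor((de - lo) / bin_width).astype(int), 0, nbins - 1)
    counts = np.zeros((nbins, nbins), dtype=int)
    np.add.at(counts, (ii, jj), 1)
    return counts, edges, edges.copy()


# -------------------------------------------------------------- H-bond table

#: elements treated as H-bond donors (when carrying H) and acceptors
_DONOR_ELEMENTS = {"N", "O", "F"}
_ACCEPTOR_ELEMENTS = {"N", "O", "F", "Cl"}


@dataclass(frozen=True)
class HBondRecord:
    """One D-H...A contact found in the packed crystal."""

    donor: str
    hydrogen: str
    acceptor: str
    symmetry_op: str
    translation: Tuple[int, int, int]
    geometry: HBondGeometry
    intramolecular: bool
    ring_size: Optional[int] = None  # only for intramolecular contacts


def hbond_table(
    s: CrystalStructure,
    d_da_max: float = 3.5,
    d_ha_max: float = 2.7,
    angle_min: float = 120.0,
    shell: int = 1,
) -> List[HBondRecord]:
    """Geometric hydrogen-bond table of a crystal structure.

    Enumerates D-H...A triples between the asymmetric unit's donors
    (N/O/F with a covalently bonded H) and acceptor images generated
    by every symmetry operator plus lattice translations within
    ±*shell* cells.  A contact is kept when d(D...A) <= d_da_max,
    d(H...A) <= d_ha_max and the D-H...A angle >= angle_min.
    Identity images give intramolecular records (with the H-bond ring
    size); acceptors fewer than three covalent bonds from the donor
    are skipped.
    """
    mol = s.asymmetric_unit
    if not any(a.element == "H" for a in mol.atoms):
        raise ValueError("structure has no hydrogen atoms; H positions are required")
    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    g.add_edges_from((i, j) for i, j, _ in mol.bonds)
    donors: List[Tuple[int, int]] = []
    for i, j, _ in mol.bonds:
        for d, h in ((i, j), (j, i)):
            if mol.atoms[d].element in _DONOR_ELEMENTS and mol.atoms[h].element == "H":
                donors.append((d, h))
    images = expand_symmetry(s, shell=shell)
    acceptors = [img for img in images if img.atom.element in _ACCEPTOR_ELEMENTS]
    records: List[HBondRecord] = []
    for d_idx, h_idx in donors:
        D, H = mol.atoms[d_idx].coords, mol.atoms[h_idx].coords
        for img in acceptors:
            if img.is_identity_image:
                try:
                    sep = nx.shortest_path_length(g, d_idx, img.source)
                except nx.NetworkXNoPath:
                    sep = None
                if sep is not None and sep < 3:
                    continue  # covalent neighbourhood, not an H-bond
            A = img.atom.coords
            d_da = float(np.linalg.norm(D - A))
            if d_da < 0.5 or d_da > d_da_max:
                continue
            geo = hbond_geometry(D, H, A)
            if geo.d_ha > d_ha_max or geo.angle_dha < angle_min:
                continue
            intra = img.is_identity_image
            ring = hbond_ring_size(mol, h_idx, img.source) if intra else None
            records.append(
                HBondRecord(
                    donor=mol.atoms[d_idx].label,
                    hydrogen=mol.atoms[h_idx].label,
                    acceptor=img.atom.label,
                    symmetry_op=img.op,
                    translation=img.translation,
                    geometry=geo,
                    intramolecular=intra,
                    ring_size=ring,
                )
            )
    records.sort(key=lambda r: (not r.intramolecular, r.geometry.d_da))
    return records


# ------------------------------------------------------------------- CSV I/O

def read_contact_table(path) -> ContactTable:
    """Read a contact table CSV with columns kind,x,y,value.

    ``kind`` is "S" for surface rows (y empty) and "C" for merged
    contact rows.
    """
    df = pd.read_csv(path, dtype={"kind": str, "x": str, "y": str})
    surface = {
        r.x: float(r.value) for r in df[df["kind"] == "S"].itertuples()
    }
    contacts = {
        _pair(r.x, r.y): float(r.value) for r in df[df["kind"] == "C"].itertuples()
    }
    return ContactTable(surface=surface, contacts=contacts)


def write_contact_table(table: ContactTable, path) -> None:
    rows = [("S", x, "", v) for x, v in table.surface.items()]
    rows += [("C", x, y, v) for (x, y), v in table.contacts.items()]
    pd.DataFrame(rows, columns=["kind", "x", "y", "value"]).to_csv(Path(path), index=False)
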