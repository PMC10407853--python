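"""Planted synthetic inputs for every analysis stage.

The ensemble generator builds a deliberately abstract test molecule:
disjoint anchor groups (helix marker triad, 3-10 triad, turn quartet,
and two H-bond donor/acceptor chains closing 10- and 7-membered
pseudo-rings) whose geometries are drawn per conformer from the ideal
templates of :mod:`foldmimic.turnfit` when a motif is planted, and
from an extended chain when it is not.  Because the groups are
spatially independent, any combination of motif labels can be planted
on one conformer — mirroring real ensembles where the motif
percentages overlap — and zero-noise classification recovers the
planted labels exactly.  Covalent bonds within the H-bond chains are
topological (ring-size bookkeeping), not geometrically idealized.

The toy-crystal generator inverts the H-bond geometry equations to
plant one intramolecular N-H...O contact at a requested D...A
distance and D-H...A angle, plus one lattice-translation-generated
intermolecular contact, inside a P1 cell.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .chemid import CrystalCell
from .mimicry import AnchorSet
from .structio import Atom, Conformer, CrystalStructure, Ensemble, Molecule
from .turnfit import build_backbone, ideal_helix, ideal_turn
from .xtalstats import ContactTable, random_contacts

__all__ = [
    "PlantSpec",
    "gen_ensemble",
    "gen_toy_crystal",
    "gen_contact_table",
    "planted_molecule",
]

MOTIFS = ("alpha", "beta", "three10")


@dataclass(frozen=True)
class PlantSpec:
    """What to plant: motif fractions, ensemble size, noise, energies.

    Fractions may overlap (a conformer can carry several motif labels).
    ``global_min`` names the motif owning the lowest-energy conformer
    (None: indifferent).  ``energy_spread`` is the width (kcal/mol) of
    the uniform energy band above the minimum; the default 9 keeps the
    whole ensemble inside a 10 kcal/mol window.
    """

    n: int = 100
    f_alpha: float = 0.0
    f_beta: float = 0.0
    f_three10: float = 0.0
    sigma: float = 0.0
    global_min: Optional[str] = None
    energy_spread: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for f in (self.f_alpha, self.f_beta, self.f_three10):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0, 1]")
        if self.global_min is not None and self.global_min not in MOTIFS:
            raise ValueError(f"global_min must be one of {MOTIFS}")
        if self.energy_spread <= 0:
            raise ValueError("energy_spread must be positive")

    @property
    def fractions(self) -> Dict[str, float]:
        return {"alpha": self.f_alpha, "beta": self.f_beta, "three10": self.f_three10}


# ------------------------------------------------------------ test molecule

# atom index layout of the planted molecule
_HELIX = (0, 1, 2)          # helix marker carbons (i, i+4, i+7)
_THREE10 = (3, 4, 5)        # 3-10 marker carbons (i, i+2, i+4)
_QUARTET = (6, 7, 8, 9)     # turn quartet C1, C2, C3, N4
_C10_ACC = 10               # beta-turn H-bond acceptor O
_C10_CHAIN = tuple(range(11, 18))
_NHB = (18, 19)             # donor N, H  (the "NH_B" amide)
_GAMMA_B_ACC = 20           # 7-ring acceptor O reachable from NH_B
_NHA_ACC = 21               # 7-ring acceptor O for NH_A
_NHA_CHAIN = (22, 23, 24, 25)
_NHA = (26, 27)             # donor N, H  (the "NH_A" amide)
_N_ATOMS = 28

# rigid offsets keeping the anchor groups spatially independent
_OFFSETS = {"helix": (0.0, 0.0, 0.0), "three10": (40.0, 0.0, 0.0),
            "quartet": (80.0, 0.0, 0.0), "c10": (120.0, 0.0, 0.0),
            "nha": (160.0, 0.0, 0.0)}


def planted_molecule() -> Tuple[Molecule, AnchorSet]:
    """The fixed topology shared by all generated conformers."""
    spec = (
        [("C", "HX")] * 3 + [("C", "TH")] * 3
        + [("C", "Q1"), ("C", "Q2"), ("C", "Q3"), ("N", "Q4")]
        + [("O", "OB")] + [("C", "CB")] * 7 + [("N", "NB"), ("H", "HB")]
        + [("O", "OG")]
        + [("O", "OA")] + [("C", "CA")] * 4 + [("N", "NA"), ("H", "HA")]
    )
    atoms = [Atom(el, f"{lab}{i}", np.zeros(3)) for i, (el, lab) in enumerate(spec)]
    bonds = [(6, 7, 1), (7, 8, 1), (8, 9, 1)]
    ring10 = (_C10_ACC,) + _C10_CHAIN + (_NHB[0],)
    bonds += [(ring10[k], ring10[k + 1], 1) for k in range(len(ring10) - 1)]
    bonds += [(_NHB[0], _NHB[1], 1)]
    bonds += [(_GAMMA_B_ACC, _C10_CHAIN[3], 1)]  # O...C...C...C-N-H = 7-ring
    ring7 = (_NHA_ACC,) + _NHA_CHAIN + (_NHA[0],)
    bonds += [(ring7[k], ring7[k + 1], 1) for k in range(len(ring7) - 1)]
    bonds += [(_NHA[0], _NHA[1], 1)]
    molecule = Molecule(atoms=atoms, bonds=bonds)
    anchors = AnchorSet(
        helix=_HELIX,
        three10=_THREE10,
        turn_quartet=_QUARTET,
        d_alpha_pair=(_QUARTET[0], _QUARTET[3]),
        nhb=_NHB,
        nhb_acceptors=(_C10_ACC, _GAMMA_B_ACC),
        nha=_NHA,
        nha_acceptors=(_NHA_ACC,),
    )
    return molecule, anchors


def _arc(p: np.ndarray, q: np.ndarray, n: int, height: float = 3.5) -> np.ndarray:
    """n points on a half-ellipse from p to q bulging out of plane.

    Keeps the chain atoms clear of the donor hydrogen and of each
    other even when the p -> q chord is short.
    """
    chord = q - p
    mid = (p + q) / 2.0
    u = chord / max(np.linalg.norm(chord), 1e-9)
    theta = math.pi - np.linspace(0.0, math.pi, n + 2)[1:-1]
    pts = (
        mid
        + (np.linalg.norm(chord) / 2.0) * np.cos(theta)[:, None] * u
        + height * np.sin(theta)[:, None] * np.array([0.0, 0.0, 1.0])
    )
    return pts


def _hbond_site(d_ha: float, angle_dha: float) -> np.ndarray:
    """Acceptor position for a donor N at (1,0,0), H at the origin."""
    a = math.radians(angle_dha)
    return d_ha * np.array([math.cos(a), math.sin(a), 0.0])


def _base_coords(labels: Set[str], templates: Dict[str, np.ndarray]) -> np.ndarray:
    """Noise-free conformer coordinates for one planted label set."""
    x = np.zeros((_N_ATOMS, 3))
    x[list(_HELIX)] = templates["helix" if "alpha" in labels else "helix_off"]
    x[list(_THREE10)] = templates["310" if "three10" in labels else "310_off"]
    x[list(_QUARTET)] = templates["turn" if "beta" in labels else "turn_off"]
    x[list(_HELIX)] += _OFFSETS["helix"]
    x[list(_THREE10)] += _OFFSETS["three10"]
    x[list(_QUARTET)] += _OFFSETS["quartet"]

    # NH_B block: donor N at (1,0,0), H at origin (local frame)
    nb = np.array([1.0, 0.0, 0.0])
    hb = np.zeros(3)
    acc_near = _hbond_site(1.97, 147.0)
    acc_far = _hbond_site(6.0, 147.0)
    o_c10 = acc_near if "beta" in labels else acc_far
    o_gb = (acc_near if "alpha" in labels else acc_far) * np.array([1.0, -1.0, 1.0])
    x[_NHB[0]], x[_NHB[1]], x[_C10_ACC], x[_GAMMA_B_ACC] = nb, hb, o_c10, o_gb
    x[list(_C10_CHAIN)] = _arc(o_c10, nb, len(_C10_CHAIN))
    x[[_NHB[0], _NHB[1], _C10_ACC, _GAMMA_B_ACC] + list(_C10_CHAIN)] += _OFFSETS["c10"]

    # NH_A block
    o_ga = acc_near if "alpha" in labels else acc_far
    x[_NHA[0]], x[_NHA[1]], x[_NHA_ACC] = nb, hb, o_ga
    x[list(_NHA_CHAIN)] = _arc(o_ga, nb, len(_NHA_CHAIN))
    x[[_NHA[0], _NHA[1], _NHA_ACC] + list(_NHA_CHAIN)] += _OFFSETS["nha"]
    return x


def _templates() -> Dict[str, np.ndarray]:
    ext8 = build_backbone([180.0] * 8, [180.0] * 8)
    ext5 = build_backbone([180.0] * 5, [180.0] * 5)
    ext4 = build_backbone([180.0] * 4, [180.0] * 4)
    return {
        "helix": ideal_helix("alpha", 8).CB[[0, 4, 7]],
        "helix_off": ext8.CB[[0, 4, 7]],
        "310": ideal_helix("three10", 5).CB[[0, 2, 4]],
        "310_off": ext5.CB[[0, 2, 4]],
        "turn": ideal_turn("II").CA,
        "turn_off": ext4.CA,
    }


def gen_ensemble(spec: PlantSpec) -> Tuple[Ensemble, AnchorSet, List[Set[str]]]:
    """Generate a planted conformer ensemble.

    Returns ``(ensemble, anchors, labels)`` where ``labels[i]`` is the
    set of motifs planted on conformer i.  Motif membership is drawn
    without replacement to hit ``round(f * n)`` members exactly; the
    designated global-minimum conformer gets energy 0 and the rest are
    uniform on (0, energy_spread].  Gaussian coordinate noise of width
    ``sigma`` is applied to every atom.  Raises on a contradictory
    spec (a ``global_min`` motif with no planted members).
    """
    rng = np.random.default_rng(spec.seed)
    molecule, anchors = planted_molecule()
    labels: List[Set[str]] = [set() for _ in range(spec.n)]
    for motif, f in spec.fractions.items():
        k = int(round(f * spec.n))
        for i in rng.permutation(spec.n)[:k]:
            labels[i].add(motif)
    if spec.global_min is not None:
        owners = [i for i, lab in enumerate(labels) if spec.global_min in lab]
        if not owners:
            raise ValueError(
                f"global_min={spec.global_min!r} requested but no conformer carries it"
            )
        # prefer a conformer carrying only the designated motif, so the
        # summary's global-minimum label is unambiguous
        pure = [i for i in owners if labels[i] == {spec.global_min}]
        min_idx = int(pure[0] if pure else owners[0])
    else:
        min_idx = 0
    energies = rng.uniform(0.0, spec.energy_spread, size=spec.n)
    energies[min_idx] = 0.0
    templates = _templates()
    conformers = []
    for i in range(spec.n):
        x = _base_coords(labels[i], templates)
        if spec.sigma > 0:
            x = x + rng.normal(0.0, spec.sigma, size=x.shape)
        conformers.append(Conformer(id=f"conf{i}", coords=x, energy=float(energies[i])))
    ensemble = Ensemble(molecule=molecule, conformers=conformers, energy_method="planted")
    return ensemble, anchors, labels


# ------------------------------------------------------------- toy crystal

def _solve_d_ha(d_da: float, angle_dha: float, d_dh: float = 1.0) -> float:
    """H...A distance from D...A, the D-H...A angle and the D-H bond."""
    c = math.cos(math.radians(angle_dha))
    disc = c * c - 1.0 + (d_da / d_dh) ** 2
    if disc < 0:
        raise ValueError(f"infeasible H-bond geometry (d_da={d_da}, angle={angle_dha})")
    d_ha = d_dh * (c + math.sqrt(disc))
    if d_ha <= 0:
        raise ValueError("infeasible H-bond geometry: no positive H...A distance")
    return d_ha


def gen_toy_crystal(
    d_da: float = 2.727,
    angle_dha: float = 147.2,
    inter_d_da: float = 2.843,
    inter_angle_dha: float = 166.1,
) -> CrystalStructure:
    """A P1 toy crystal with one planted intramolecular N-H...O bond.

    The intramolecular contact closes a 10-membered pseudo-ring at
    exactly the requested D...A distance and D-H...A angle; a second
    amide donates to the O of the (x, y-1, z) lattice neighbour at the
    ``inter_*`` geometry, forming a chain along b.  Raises when the
    requested geometry is infeasible (no solution, or atoms closer
    than van der Waals contact allows).
    """
    d_ha = _solve_d_ha(d_da, angle_dha)
    if d_ha < 1.3 or d_da < 2.4:
        raise ValueError(
            f"infeasible H-bond geometry: atoms clash (d_ha={d_ha:.2f}, d_da={d_da})"
        )
    inter_d_ha = _solve_d_ha(inter_d_da, inter_angle_dha)
    if inter_d_ha < 1.3 or inter_d_da < 2.4:
        raise ValueError("infeasible intermolecular H-bond geometry: atoms clash")
    cell = CrystalCell(a=16.0, b=7.0, c=16.0, Z=1, space_group="P1")

    # intramolecular motif: H1 at origin, N1 at (1,0,0)
    n1 = np.array([1.0, 0.0, 0.0])
    h1 = np.zeros(3)
    o1 = _hbond_site(d_ha, angle_dha)
    chain1 = _arc(o1, n1, 7)

    # intermolecular motif: N2-H2 pointing -y at the O2 image shifted by -b
    n2 = np.array([5.0, 2.0, 0.0])
    h2 = n2 + np.array([0.0, -1.0, 0.0])
    tilt = math.radians(180.0 - inter_angle_dha)
    u = np.array([math.sin(tilt), -math.cos(tilt), 0.0])
    o2 = h2 + inter_d_ha * u + np.array([0.0, cell.b, 0.0])

    coords = np.vstack([o1, chain1, n1, h1, n2, h2, o2])
    elements = ["O"] + ["C"] * 7 + ["N", "H", "N", "H", "O"]
    labels = ["O1", "C1", "C2", "C3", "C4", "C5", "C6", "C7", "N1", "H1", "N2", "H2", "O2"]
    # centre the molecule in the cell to keep images apart
    coords = coords + np.array([cell.a / 2 - 2.0, 2.5, cell.c / 2])
    atoms = [Atom(el, lab, xyz) for el, lab, xyz in zip(elements, labels, coords)]
    bonds = [(0, 1, 1)] + [(k, k + 1, 1) for k in range(1, 7)] + [(7, 8, 1), (8, 9, 1)]
    bonds += [(10, 11, 1), (5, 10, 1), (4, 12, 1)]  # N2-H2; N2 and O2 tied to the chain
    molecule = Molecule(atoms=atoms, bonds=bonds)
    # clash check between non-bonded atoms
    bonded = {(min(i, j), max(i, j)) for i, j, _ in bonds}
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if (i, j) in bonded:
                continue
            if np.linalg.norm(coords[i] - coords[j]) < 0.75:
                raise ValueError(
                    f"infeasible geometry: atoms {labels[i]} and {labels[j]} clash"
                )
    return CrystalStructure(cell=cell, asymmetric_unit=molecule, symmetry_ops=["x, y, z"])


# ------------------------------------------------------------ contact table

def gen_contact_table(
    elements: Sequence[str], seed: int = 0, mode: str = "random"
) -> ContactTable:
    """Random surface composition and contact fractions.

    ``mode="consistent"`` sets C = the random-contact expectation of S,
    so every enrichment ratio is exactly 1.
    """
    if not elements:
        raise ValueError("need at least one element")
    rng = np.random.default_rng(seed)
    s_vals = rng.dirichlet(np.full(len(elements), 5.0)) * 100.0
    surface = dict(zip(elements, map(float, s_vals)))
    if mode == "consistent":
        contacts = random_contacts(surface)
    elif mode == "random":
        pairs = list(random_contacts(surface))
        c_vals = rng.dirichlet(np.full(len(pairs), 5.0)) * 100.0
        contacts = dict(zip(pairs, map(float, c_vals)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ContactTable(surface=surface, contacts=contacts)
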