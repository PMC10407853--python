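"""Ideal secondary-structure templates and turn-type RMSD fitting.

Backbones are generated from internal coordinates (sequential NeRF
placement with fixed bond lengths and angles), which gives exact
control over phi/psi/omega.  Four-residue beta-turn templates use the
classical Venkatachalam central dihedrals; helix templates use the
textbook (phi, psi) pairs.  Side-chain marker carbons (Cbeta) are
placed at tetrahedral positions and serve as the anchor points whose
i/i+4/i+7 (or i/i+2/i+4) spacings define helix mimicry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .geomcore import dihedral, superpose
from .structio import Conformer

__all__ = [
    "BackboneGeometry",
    "PeptideTemplate",
    "FitResult",
    "build_backbone",
    "ideal_turn",
    "ideal_helix",
    "three10_reference_distances",
    "fit_turn_types",
    "TURN_DIHEDRALS",
]

# canonical central (phi2, psi2, phi3, psi3) of the four turn types;
# the primed types are exact sign inversions (mirror images) of their parents
TURN_DIHEDRALS: Dict[str, Tuple[float, float, float, float]] = {
    "I": (-60.0, -30.0, -90.0, 0.0),
    "II": (-60.0, 120.0, 80.0, 0.0),
    "I'": (60.0, 30.0, 90.0, 0.0),
    "II'": (60.0, -120.0, -80.0, 0.0),
}

HELIX_DIHEDRALS = {"alpha": (-57.0, -47.0), "three10": (-49.0, -26.0)}


@dataclass(frozen=True)
class BackboneGeometry:
    """Fixed internal-coordinate constants of the builder (A, degrees)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    ca_cb: float = 1.530
    # tetrahedral backbone angle at Calpha: with the canonical helix
    # dihedrals this reproduces the 3.6 residues/turn, 1.5 A rise helix
    # whose i/i+4/i+7 Cbeta spacings are the mimicry references
    ang_n_ca_c: float = 109.5
    ang_ca_c_n: float = 116.0
    ang_c_n_ca: float = 121.0
    ang_ca_c_o: float = 120.5
    ang_n_ca_cb: float = 110.5
    # improper torsion C-N-CA-CB fixing the L-configuration at Calpha
    tor_cb: float = -122.55


DEFAULT_GEOMETRY = BackboneGeometry()


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float,
          torsion: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees)."""
    th, chi = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(th), bond * math.sin(th) * math.cos(chi),
         bond * math.sin(th) * math.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class PeptideTemplate:
    """An ideal backbone: per-residue N/CA/C/O plus Cbeta markers."""

    name: str
    phi: List[float]
    psi: List[float]
    omega: List[float]
    N: np.ndarray
    CA: np.ndarray
    C: np.ndarray
    O: np.ndarray
    CB: np.ndarray

    @property
    def n_residues(self) -> int:
        return len(self.phi)

    def atom(self, name: str, residue: int) -> np.ndarray:
        """Coordinate of backbone atom *name* ("N", "CA", "C", "O", "CB")
        of 0-based *residue*."""
        return getattr(self, name)[residue]

    def backbone(self, residues: Optional[Sequence[int]] = None) -> np.ndarray:
        """N, CA, C coordinates of the selected residues, concatenated."""
        residues = range(self.n_residues) if residues is None else residues
        return np.concatenate([[self.N[i], self.CA[i], self.C[i]] for i in residues])

    def measured_dihedrals(self) -> Tuple[List[float], List[float], List[float]]:
        """Re-measure (phi, psi, omega) from the built coordinates."""
        n = self.n_residues
        phi = [math.nan] + [
            dihedral(self.C[i - 1], self.N[i], self.CA[i], self.C[i]) for i in range(1, n)
        ]
        psi = [
            dihedral(self.N[i], self.CA[i], self.C[i], self.N[i + 1]) for i in range(n - 1)
        ] + [math.nan]
        omega = [
            dihedral(self.CA[i], self.C[i], self.N[i + 1], self.CA[i + 1])
            for i in range(n - 1)
        ] + [math.nan]
        return phi, psi, omega


def build_backbone(
    phi: Sequence[float],
    psi: Sequence[float],
    omega: Optional[Sequence[float]] = None,
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
    name: str = "backbone",
) -> PeptideTemplate:
    """Build an ideal peptide backbone from dihedrals.

    ``phi[0]`` is geometrically unused (there is no preceding carbonyl)
    but must still be supplied; omega defaults to all-trans (180).
    Dihedrals must lie in (-180, 180].
    """
    n = len(phi)
    if n < 2 or len(psi) != n:
        raise ValueError("need phi and psi for at least 2 residues")
    omega = list(omega) if omega is not None else [180.0] * n
    for seq in (phi, psi, omega):
        for v in seq:
            if not -180.0 < v <= 180.0:
                raise ValueError(f"dihedral {v} outside (-180, 180]")
    g = geometry
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    # first residue in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (g.n_ca, 0.0, 0.0)
    th = math.radians(180.0 - g.ang_n_ca_c)
    C[0] = CA[0] + g.ca_c * np.array([math.cos(th), math.sin(th), 0.0])
    for i in range(1, n):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], g.c_n, g.ang_ca_c_n, psi[i - 1])
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], g.n_ca, g.ang_c_n_ca, omega[i - 1])
        C[i] = _nerf(C[i - 1], N[i], CA[i], g.ca_c, g.ang_n_ca_c, phi[i])
    O = np.zeros((n, 3))
    CB = np.zeros((n, 3))
    for i in range(n):
        # carbonyl O anti to the next N (psi + 180 about CA-C)
        o_tor = psi[i] + 180.0
        o_tor -= 360.0 if o_tor > 180.0 else 0.0
        O[i] = _nerf(N[i], CA[i], C[i], g.c_o, g.ang_ca_c_o, o_tor)
        CB[i] = _nerf(C[i], N[i], CA[i], g.ca_cb, g.ang_n_ca_cb, g.tor_cb)
    return PeptideTemplate(
        name=name, phi=list(phi), psi=list(psi), omega=omega, N=N, CA=CA, C=C, O=O, CB=CB
    )


def _canon_type(turn_type: str) -> str:
    t = turn_type.strip().replace("′", "'").upper()
    if t not in TURN_DIHEDRALS:
        raise ValueError(f"unknown beta-turn type {turn_type!r} (expected I, II, I', II')")
    return t


def ideal_turn(turn_type: str) -> PeptideTemplate:
    """Four-residue ideal beta-turn of type I, II, I' or II'.

    Central residues carry the canonical dihedrals; the terminal
    residues are extended (phi = psi = 180) and omega is trans
    throughout.
    """
    t = _canon_type(turn_type)
    phi2, psi2, phi3, psi3 = TURN_DIHEDRALS[t]
    return build_backbone(
        phi=[180.0, phi2, phi3, 180.0],
        psi=[180.0, psi2, psi3, 180.0],
        name=f"beta-turn {t}",
    )


def ideal_helix(kind: str, n_residues: int) -> PeptideTemplate:
    """Ideal alpha (phi,psi = -57,-47) or 3-10 (-49,-26) helix.

    An alpha helix needs >= 8 residues to expose the i/i+4/i+7 anchor
    triple; a 3-10 helix needs >= 5 for i/i+2/i+4.
    """
    if kind not in HELIX_DIHEDRALS:
        raise ValueError(f"unknown helix kind {kind!r} (expected 'alpha' or 'three10')")
    minimum = 8 if kind == "alpha" else 5
    if n_residues < minimum:
        raise ValueError(f"{kind} helix template needs at least {minimum} residues")
    phi, psi = HELIX_DIHEDRALS[kind]
    return build_backbone(
        phi=[phi] * n_residues, psi=[psi] * n_residues, name=f"{kind} helix"
    )


def three10_reference_distances() -> Tuple[float, float, float]:
    """Reference Cbeta spacings (i,i+2), (i,i+4), (i+2,i+4) of an ideal
    3-10 helix, in Angstrom.  These play the role the printed
    6.2/10.3/5.8 A triple plays for the alpha helix."""
    t = ideal_helix("three10", 5)
    cb = t.CB
    return (
        float(np.linalg.norm(cb[0] - cb[2])),
        float(np.linalg.norm(cb[0] - cb[4])),
        float(np.linalg.norm(cb[2] - cb[4])),
    )


@dataclass(frozen=True)
class FitResult:
    """RMSD against each beta-turn template and the best-fitting type."""

    rmsd: Dict[str, float]
    best: str

    def __post_init__(self) -> None:
        if self.best != min(self.rmsd, key=self.rmsd.get):
            raise ValueError("best type does not attain the minimum rmsd")


MappingPair = Tuple[int, Tuple[int, str]]


def fit_turn_types(
    conformer: Union[Conformer, np.ndarray], mapping: Sequence[MappingPair]
) -> FitResult:
    """Kabsch-fit a conformer against all four ideal beta-turn types.

    *mapping* pairs a conformer atom index with a template backbone
    atom ``(residue, name)``, e.g. ``(12, (1, "CA"))``.  At least three
    pairs are required.  Ties for the best type break toward the
    conventional order I, II, I', II'.
    """
    coords = conformer.coords if isinstance(conformer, Conformer) else np.asarray(conformer, float)
    if len(mapping) < 3:
        raise ValueError("need at least 3 mapped atom pairs")
    idx = [int(i) for i, _ in mapping]
    if max(idx) >= len(coords) or min(idx) < 0:
        raise ValueError("mapping references conformer atoms that do not exist")
    X = coords[idx]
    rmsds: Dict[str, float] = {}
    for t in TURN_DIHEDRALS:
        template = ideal_turn(t)
        try:
            Y = np.array([template.atom(name, res) for _, (res, name) in mapping])
        except (IndexError, AttributeError) as exc:
            raise ValueError(f"mapping references missing template atoms: {exc}") from exc
        rmsds[t] = superpose(X, Y).rmsd
    best = min(TURN_DIHEDRALS, key=lambda t: rmsds[t])
    return FitResult(rmsd=rmsds, best=best)
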