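"""Geometry primitives for conformational and crystal-packing analysis.

Distances, signed torsions, least-squares planes, reflection-free
Kabsch superposition, hydrogen-bond geometry and the covalent ring
size closed by an intramolecular H-bond (the C10/C7 nomenclature of
beta- and gamma-turns), and pi-stacking descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence, Tuple

import networkx as nx
import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .structio import Molecule

__all__ = [
    "HBondGeometry",
    "SuperpositionResult",
    "dihedral",
    "lsq_plane_max_deviation",
    "superpose",
    "hbond_geometry",
    "hbond_ring_size",
    "pi_stack_geometry",
]


@dataclass(frozen=True)
class HBondGeometry:
    """D-H...A geometry: distances in Angstrom, angle at H in degrees."""

    d_da: float
    d_ha: float
    angle_dha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_dha <= 180.0:
            raise ValueError(f"D-H...A angle {self.angle_dha} outside [0, 180]")
        # triangle consistency with a ~1.0 A covalent D-H bond
        if self.d_ha >= self.d_da + 1.2:
            raise ValueError("H...A distance inconsistent with D...A (H too far from donor)")


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid map ``y ~ R x + t`` with its residual RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def transform(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


def _as_points(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite coordinates")
    return a


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    Range (-180, 180]; a trans (anti-periplanar) arrangement gives 180.
    Raises ``ValueError`` when three consecutive points are collinear
    (the torsion is then undefined).
    """
    p1, p2, p3, p4 = map(_as_points, (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 * max(1.0, np.linalg.norm(b1) * nb2) or np.linalg.norm(
        n2
    ) < 1e-9 * max(1.0, nb2 * np.linalg.norm(b3)):
        raise ValueError("torsion undefined: three consecutive points are collinear")
    ang = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2)))
    return 180.0 if ang <= -180.0 + 1e-12 else float(ang)


def lsq_plane_max_deviation(points) -> Tuple[np.ndarray, float, int]:
    """Best least-squares plane of >= 3 points.

    Returns ``(unit normal, max |signed deviation| in A, index of max)``.
    The plane passes through the centroid and minimizes the sum of
    squared orthogonal distances (smallest principal component of the
    centered cloud); deviations are signed along the returned normal.
    """
    pts = _as_points(points)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("need at least 3 points in 3D")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10 * max(1.0, s[0]):
        raise ValueError("plane undefined: points are collinear")
    normal = vt[2]
    dev = centered @ normal
    idx = int(np.argmax(np.abs(dev)))
    return normal, float(abs(dev[idx])), idx


def superpose(X, Y) -> SuperpositionResult:
    """Least-squares rigid superposition of X onto Y (Kabsch).

    The rotation is constrained to be proper (det = +1): a mimicry
    comparison must never silently mirror chirality, so mirrored
    templates have to be supplied explicitly.  RMSD is the root mean
    squared residual after the optimal fit.
    """
    X, Y = _as_points(X), _as_points(Y)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("point sets must be equal-length N x 3 arrays")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    if np.linalg.matrix_rank(X0, tol=1e-8 * max(1.0, np.abs(X0).max())) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    H = X0.T @ Y0
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    resid = Y0 - X0 @ R.T
    rmsd = float(np.sqrt((resid**2).sum() / n))
    t = yc - R @ xc
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def hbond_geometry(D, H, A) -> HBondGeometry:
    """Measure D-H...A geometry from donor, hydrogen and acceptor positions."""
    D, H, A = map(_as_points, (D, H, A))
    hd, ha = D - H, A - H
    nhd, nha = np.linalg.norm(hd), np.linalg.norm(ha)
    if nhd < 1e-6 or nha < 1e-6 or np.linalg.norm(D - A) < 1e-6:
        raise ValueError("coincident points: H-bond geometry undefined")
    cosang = np.clip(np.dot(hd, ha) / (nhd * nha), -1.0, 1.0)
    return HBondGeometry(
        d_da=float(np.linalg.norm(D - A)),
        d_ha=float(nha),
        angle_dha=float(np.degrees(np.arccos(cosang))),
    )


def hbond_ring_size(m: "Molecule", donor_h: int, acceptor: int) -> int:
    """Atoms in the pseudo-cycle closed by an intramolecular H-bond.

    Counts the atoms on the shortest covalent path from the acceptor to
    the donor hydrogen, inclusive; the H...A contact itself closes the
    ring.  A classical beta-turn H-bond gives 10 (C10); a gamma-turn
    gives 7 (C7).  BFS shortest path, ties broken by lowest atom index.
    """
    if m.atoms[donor_h].element != "H":
        raise ValueError(f"atom {donor_h} is not a hydrogen")
    g = nx.Graph()
    g.add_nodes_from(range(len(m.atoms)))
    g.add_edges_from((i, j) for i, j, _ in m.bonds)
    if g.degree(donor_h) != 1:
        raise ValueError(f"donor hydrogen {donor_h} must be bonded to exactly one heavy atom")
    try:
        # deterministic BFS: neighbors visited in index order
        path = nx.shortest_path(g, source=acceptor, target=donor_h)
    except nx.NetworkXNoPath:
        raise ValueError("acceptor and donor hydrogen are in different connected components")
    return len(path)


def pi_stack_geometry(ring_a, ring_b) -> Tuple[float, float]:
    """Centroid-centroid distance (A) and interplane angle (deg) of two rings.

    Centroids are unweighted means; the angle between least-squares
    plane normals is folded into [0, 90], the crystallographic
    convention for reporting stacking geometry.
    """
    a, b = _as_points(ring_a), _as_points(ring_b)
    na, _, _ = lsq_plane_max_deviation(a)
    nb, _, _ = lsq_plane_max_deviation(b)
    dist = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    cosang = abs(float(np.clip(np.dot(na, nb), -1.0, 1.0)))
    return dist, float(np.degrees(np.arccos(cosang)))
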