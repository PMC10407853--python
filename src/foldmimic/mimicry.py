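"""Conformer classification: alpha-helix / beta-turn / 3-10-helix mimicry.

A conformer mimics an alpha helix when three anchor atoms reproduce
the i/i+4/i+7 side-chain spacings of the ideal helix (references 6.2,
10.3, 5.8 A); it mimics a beta turn when the anchor distance d_alpha
is below 7 A and the C1-C2-C3-N4 torsion |beta| is below 60 deg; the
3-10 motif uses i/i+2/i+4 anchors against spacings measured once on
an ideal 3-10 template.  Intramolecular H-bond patterns (the C10 ring
of a beta turn, the C7 gamma-turn pair that signs an alpha helix) are
detected alongside and reported per conformer.  Ensemble summaries
report the percentage of conformers passing each motif within a
10 kcal/mol energy window, motifs not being mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chemid import round_half_up
from .geomcore import HBondGeometry, dihedral, hbond_geometry, hbond_ring_size
from .structio import Conformer, Ensemble, Molecule
from . import turnfit

__all__ = [
    "AnchorSet",
    "MotifCriteria",
    "HBondPattern",
    "ConformerLabel",
    "EnsembleSummary",
    "filter_energy_window",
    "classify_alpha",
    "classify_beta",
    "classify_310",
    "detect_hbond_patterns",
    "label_conformer",
    "summarize",
]

#: energy tie threshold (kcal/mol) below which two minima are "the same"
ENERGY_TIE = 1e-6


@dataclass(frozen=True)
class AnchorSet:
    """Atom selections (0-based) that instantiate the classifier.

    All fields are optional: a classifier raises when asked about a
    motif whose anchors are unset.  ``nhb``/``nha`` name the two amide
    donors of the scaffold as ``(heavy atom, hydrogen)``; each has its
    own list of acceptor candidates.
    """

    helix: Optional[Tuple[int, int, int]] = None  # Ci, Ci+4, Ci+7
    turn_quartet: Optional[Tuple[int, int, int, int]] = None  # C1, C2, C3, N4
    d_alpha_pair: Optional[Tuple[int, int]] = None
    three10: Optional[Tuple[int, int, int]] = None  # i, i+2, i+4
    nhb: Optional[Tuple[int, int]] = None  # donor heavy, H
    nhb_acceptors: Tuple[int, ...] = ()
    nha: Optional[Tuple[int, int]] = None
    nha_acceptors: Tuple[int, ...] = ()

    def validate(self, molecule: Molecule) -> None:
        n = len(molecule.atoms)
        groups = [
            self.helix, self.turn_quartet, self.d_alpha_pair, self.three10,
            self.nhb, self.nha, self.nhb_acceptors, self.nha_acceptors,
        ]
        for grp in groups:
            for idx in grp or ():
                if not 0 <= idx < n:
                    raise ValueError(f"anchor index {idx} out of range for {n} atoms")
        for donor in (self.nhb, self.nha):
            if donor is not None and molecule.atoms[donor[1]].element != "H":
                raise ValueError(f"anchor atom {donor[1]} must be a hydrogen")
        if self.turn_quartet is not None and len(set(self.turn_quartet)) != 4:
            raise ValueError("turn quartet indices must be distinct")


def _default_three10_ref() -> Tuple[float, float, float]:
    return turnfit.three10_reference_distances()


@dataclass(frozen=True)
class MotifCriteria:
    """Thresholds of the mimicry classifier.

    Reference distances are in Angstrom, angles in degrees, the energy
    window in kcal/mol.  The helix references are the literature
    i/i+4/i+7 values; the 3-10 references default to spacings measured
    on the ideal 3-10 template.  The beta-turn test follows the printed
    condition (d_alpha and |beta| only); ``require_c10`` switches on a
    strict mode that additionally demands the 10-membered-ring H-bond.
    """

    helix_ref: Tuple[float, float, float] = (6.2, 10.3, 5.8)
    helix_tol: float = 1.0
    d_alpha_max: float = 7.0
    beta_dihedral_max: float = 60.0
    three10_ref: Tuple[float, float, float] = field(default_factory=_default_three10_ref)
    three10_tol: float = 1.0
    d_ha_max: float = 2.5
    d_da_max: float = 3.5
    angle_dha_min: float = 120.0
    require_c10: bool = False
    energy_window: float = 10.0

    def __post_init__(self) -> None:
        positive = (
            self.helix_tol, self.d_alpha_max, self.beta_dihedral_max, self.three10_tol,
            self.d_ha_max, self.d_da_max, self.angle_dha_min, self.energy_window,
            *self.helix_ref, *self.three10_ref,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("all thresholds must be positive")
        if self.helix_tol >= min(self.helix_ref) or self.three10_tol >= min(self.three10_ref):
            raise ValueError("tolerance must be smaller than the smallest reference distance")


@dataclass(frozen=True)
class HBondPattern:
    """One detected (or absent) intramolecular H-bond pattern."""

    present: bool
    acceptor: Optional[int] = None
    geometry: Optional[HBondGeometry] = None
    ring_size: Optional[int] = None


@dataclass(frozen=True)
class ConformerLabel:
    """Per-conformer classification record."""

    is_alpha: bool = False
    is_beta: bool = False
    is_310: bool = False
    helix_distances: Optional[Tuple[float, float, float]] = None
    three10_distances: Optional[Tuple[float, float, float]] = None
    d_alpha: Optional[float] = None
    beta_dihedral: Optional[float] = None
    c10: Optional[HBondPattern] = None
    gamma_nha: Optional[HBondPattern] = None
    gamma_nhb: Optional[HBondPattern] = None

    @property
    def flags(self) -> Tuple[bool, bool, bool]:
        return (self.is_alpha, self.is_beta, self.is_310)


@dataclass(frozen=True)
class EnsembleSummary:
    """Ensemble-level motif percentages and the global-minimum label."""

    compound: str
    n_conformers: int
    pct_beta: int
    pct_alpha: int
    pct_310: int
    global_minimum: str  # "alpha-helix" | "beta-turn" | "3_10-helix" | "n.d."


def filter_energy_window(ensemble: Ensemble, window: float = 10.0) -> Ensemble:
    """Keep conformers within *window* kcal/mol of the minimum (inclusive).

    Every conformer must carry an energy; the minimum is always kept.
    """
    energies = [c.energy for c in ensemble.conformers]
    if any(e is None for e in energies):
        missing = [c.id for c, e in zip(ensemble.conformers, energies) if e is None][:3]
        raise ValueError(f"conformers without energy: {missing}")
    e_min = min(energies)
    kept = [c for c in ensemble.conformers if c.energy - e_min <= window]
    return Ensemble(
        molecule=ensemble.molecule, conformers=kept, energy_method=ensemble.energy_method
    )


def _triple_distances(coords: np.ndarray, idx: Tuple[int, int, int]) -> Tuple[float, float, float]:
    a, b, c = (coords[i] for i in idx)
    return (
        float(np.linalg.norm(a - b)),
        float(np.linalg.norm(a - c)),
        float(np.linalg.norm(b - c)),
    )


def classify_alpha(
    c: Conformer, anchors: AnchorSet, crit: MotifCriteria
) -> Tuple[bool, Tuple[float, float, float]]:
    """Alpha-helix test: all three anchor distances within tolerance of
    the i/i+4/i+7 references.  Returns (flag, measured distances)."""
    if anchors.helix is None:
        raise ValueError("helix anchors not set")
    measured = _triple_distances(c.coords, anchors.helix)
    ok = all(abs(m - r) <= crit.helix_tol for m, r in zip(measured, crit.helix_ref))
    return ok, measured


def classify_310(
    c: Conformer, anchors: AnchorSet, crit: MotifCriteria
) -> Tuple[bool, Tuple[float, float, float]]:
    """3-10-helix test: i/i+2/i+4 anchor distances against the template
    references.  Returns (flag, measured distances)."""
    if anchors.three10 is None:
        raise ValueError("3-10 anchors not set")
    measured = _triple_distances(c.coords, anchors.three10)
    ok = all(abs(m - r) <= crit.three10_tol for m, r in zip(measured, crit.three10_ref))
    return ok, measured


def _find_hbond(
    molecule: Molecule,
    coords: np.ndarray,
    donor: Tuple[int, int],
    acceptors: Sequence[int],
    crit: MotifCriteria,
) -> List[HBondPattern]:
    """All acceptor candidates of one donor that pass the H-bond cutoffs."""
    d_idx, h_idx = donor
    if molecule.atoms[h_idx].element != "H":
        raise ValueError(f"donor hydrogen index {h_idx} is not a hydrogen")
    if not any({i, j} == {d_idx, h_idx} for i, j, _ in molecule.bonds):
        raise ValueError(f"donor atom {d_idx} has no bonded hydrogen {h_idx}")
    hits: List[HBondPattern] = []
    for acc in acceptors:
        geo = hbond_geometry(coords[d_idx], coords[h_idx], coords[acc])
        if (
            geo.d_ha <= crit.d_ha_max
            and geo.d_da <= crit.d_da_max
            and geo.angle_dha >= crit.angle_dha_min
        ):
            ring = hbond_ring_size(molecule, h_idx, acc)
            hits.append(HBondPattern(present=True, acceptor=acc, geometry=geo, ring_size=ring))
    return hits


def _best_of_ring(hits: List[HBondPattern], ring: int) -> HBondPattern:
    matching = [h for h in hits if h.ring_size == ring]
    if not matching:
        return HBondPattern(False)
    return min(matching, key=lambda h: h.geometry.d_ha)


def detect_hbond_patterns(
    c: Conformer, anchors: AnchorSet, crit: MotifCriteria, molecule: Molecule
) -> Dict[str, HBondPattern]:
    """Detect the motif-defining intramolecular H-bond patterns.

    Returns a dict with keys ``"c10"`` (the 10-membered-ring bond via
    the NH_B donor, the beta-turn signature), ``"gamma_nha"`` and
    ``"gamma_nhb"`` (the two 7-ring gamma-turn bonds whose joint
    presence signs an alpha-helix-like fold).  An H-bond is accepted
    when d(H...A), d(D...A) and the D-H...A angle all pass the cutoffs;
    among passing acceptor candidates the shortest H...A wins.
    """
    coords = c.coords
    out: Dict[str, HBondPattern] = {
        "c10": HBondPattern(False), "gamma_nha": HBondPattern(False),
        "gamma_nhb": HBondPattern(False),
    }
    if anchors.nhb is not None:
        hits = _find_hbond(molecule, coords, anchors.nhb, anchors.nhb_acceptors, crit)
        out["c10"] = _best_of_ring(hits, 10)
        out["gamma_nhb"] = _best_of_ring(hits, 7)
    if anchors.nha is not None:
        hits = _find_hbond(molecule, coords, anchors.nha, anchors.nha_acceptors, crit)
        out["gamma_nha"] = _best_of_ring(hits, 7)
    return out


def classify_beta(
    c: Conformer, anchors: AnchorSet, crit: MotifCriteria, molecule: Optional[Molecule] = None
) -> Tuple[bool, float, float, HBondPattern]:
    """Beta-turn test: d_alpha < max AND |torsion(C1,C2,C3,N4)| < max.

    The C10 H-bond is evaluated and reported whenever the donor anchors
    and the molecule are available; it becomes part of the condition
    only when ``crit.require_c10`` is set.  Returns
    (flag, d_alpha, beta dihedral, C10 pattern).
    """
    if anchors.turn_quartet is None or anchors.d_alpha_pair is None:
        raise ValueError("turn quartet / d_alpha anchors not set")
    coords = c.coords
    i, j = anchors.d_alpha_pair
    d_alpha = float(np.linalg.norm(coords[i] - coords[j]))
    beta = dihedral(*(coords[k] for k in anchors.turn_quartet))
    flag = d_alpha < crit.d_alpha_max and abs(beta) < crit.beta_dihedral_max
    c10 = HBondPattern(False)
    if molecule is not None and anchors.nhb is not None:
        c10 = detect_hbond_patterns(c, anchors, crit, molecule)["c10"]
    if crit.require_c10:
        flag = flag and c10.present
    return flag, d_alpha, beta, c10


def label_conformer(
    c: Conformer, anchors: AnchorSet, crit: MotifCriteria, molecule: Molecule
) -> ConformerLabel:
    """Run every classifier whose anchors are configured on one conformer."""
    kw: Dict[str, object] = {}
    if anchors.helix is not None:
        kw["is_alpha"], kw["helix_distances"] = classify_alpha(c, anchors, crit)
    if anchors.turn_quartet is not None and anchors.d_alpha_pair is not None:
        flag, d_alpha, beta, c10 = classify_beta(c, anchors, crit, molecule)
        kw.update(is_beta=flag, d_alpha=d_alpha, beta_dihedral=beta, c10=c10)
    if anchors.three10 is not None:
        kw["is_310"], kw["three10_distances"] = classify_310(c, anchors, crit)
    if anchors.nha is not None or anchors.nhb is not None:
        patterns = detect_hbond_patterns(c, anchors, crit, molecule)
        kw.setdefault("c10", patterns["c10"])
        kw["gamma_nha"] = patterns["gamma_nha"]
        kw["gamma_nhb"] = patterns["gamma_nhb"]
    return ConformerLabel(**kw)


_LABEL_NAMES = {0: "alpha-helix", 1: "beta-turn", 2: "3_10-helix"}


def _minimum_label(labels: Sequence[ConformerLabel], energies: Sequence[float]) -> str:
    e_min = min(energies)
    tied = [lab.flags for lab, e in zip(labels, energies) if e - e_min < ENERGY_TIE]
    if any(t != tied[0] for t in tied[1:]):
        return "n.d."
    flags = tied[0]
    if not any(flags):
        return "n.d."
    # a conformer can satisfy several motifs; report the most specific
    # (chain-reversal beats helix, alpha beats 3-10)
    order = (1, 0, 2)
    return _LABEL_NAMES[next(k for k in order if flags[k])]


def summarize(
    ensemble: Ensemble,
    anchors: AnchorSet,
    crit: MotifCriteria = None,
    compound: str = "",
) -> EnsembleSummary:
    """Ensemble summary: motif percentages and the global-minimum label.

    Percentages are 100 x count/n rounded half-up to integers, as such
    tables are printed; they need not sum to 100 because the motifs are
    not mutually exclusive.  The global-minimum label comes from the
    lowest-energy conformer (``"n.d."`` when unlabeled, or when
    conformers tie within 1e-6 kcal/mol with conflicting labels);
    without energies the global minimum is undefined and reported as
    ``"n.d."``.
    """
    crit = crit if crit is not None else MotifCriteria()
    if not ensemble.conformers:
        raise ValueError("empty ensemble")
    anchors.validate(ensemble.molecule)
    labels = [label_conformer(c, anchors, crit, ensemble.molecule) for c in ensemble.conformers]
    n = len(labels)
    pct = lambda k: int(round_half_up(100.0 * sum(lab.flags[k] for lab in labels) / n))
    energies = [c.energy for c in ensemble.conformers]
    gmin = (
        _minimum_label(labels, energies) if all(e is not None for e in energies) else "n.d."
    )
    return EnsembleSummary(
        compound=compound,
        n_conformers=n,
        pct_beta=pct(1),
        pct_alpha=pct(0),
        pct_310=pct(2),
        global_minimum=gmin,
    )
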