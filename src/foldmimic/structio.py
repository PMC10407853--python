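"""Structure data model and file I/O for conformer ensembles and crystals.

In-memory containers (:class:`Molecule`, :class:`Conformer`,
:class:`Ensemble`, :class:`CrystalStructure`) plus readers/writers for
multi-record SDF (via RDKit), multi-frame XYZ, PDB (via gemmi, one
model per conformer) and small-molecule CIF (via gemmi's CIF parser).

Atom indexing is 0-based internally; SDF/CIF serial numbers are
1-based at the I/O boundary.  Hydrogens are always kept explicit —
H-bond geometry needs them — and are never inferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

from .chemid import CrystalCell
from .periodic import PERIODIC_TABLE, element

__all__ = [
    "Atom",
    "Molecule",
    "Conformer",
    "Ensemble",
    "CrystalStructure",
    "ExpandedAtom",
    "read_sdf",
    "write_sdf",
    "read_xyz",
    "write_xyz",
    "read_pdb",
    "read_cif",
    "expand_symmetry",
    "perceive_bonds",
    "frac_to_cart",
    "cart_to_frac",
]

#: default SDF property holding the conformer energy, in kcal/mol
DEFAULT_ENERGY_FIELD = "E_kcal"


@dataclass(frozen=True)
class Atom:
    element: str
    label: str
    coords: np.ndarray  # Cartesian, Angstrom

    def __post_init__(self) -> None:
        if self.element not in PERIODIC_TABLE:
            raise ValueError(f"unknown element {self.element!r}")
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.label!r}: coordinates must be 3 finite numbers")
        object.__setattr__(self, "coords", c)


@dataclass
class Molecule:
    """Ordered atoms plus an undirected bond list (i, j, order), 0-based."""

    atoms: List[Atom]
    bonds: List[Tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j}) for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def elements(self) -> List[str]:
        return [a.element for a in self.atoms]

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        coords = np.asarray(coords, float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [Atom(a.element, a.label, c) for a, c in zip(self.atoms, coords)]
        return Molecule(atoms=atoms, bonds=list(self.bonds))


@dataclass
class Conformer:
    """One geometry of a parent molecule; energy in kcal/mol, optional."""

    id: str
    coords: np.ndarray
    energy: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("conformer coordinates must be N x 3")


@dataclass
class Ensemble:
    """One molecular topology with N alternative geometries."""

    molecule: Molecule
    conformers: List[Conformer]
    energy_method: str = ""

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        n = len(self.molecule.atoms)
        for c in self.conformers:
            if c.coords.shape[0] != n:
                raise ValueError(
                    f"conformer {c.id!r} has {c.coords.shape[0]} atoms, molecule has {n}"
                )

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass
class CrystalStructure:
    """Asymmetric unit in a cell with its symmetry operators.

    The asymmetric-unit molecule carries Cartesian coordinates;
    ``fractional`` holds the same positions in cell coordinates.
    Operator strings are xyz triplets ("x, y, z"; "-x, y+1/2, -z"...).
    """

    cell: CrystalCell
    asymmetric_unit: Molecule
    symmetry_ops: List[str] = field(default_factory=lambda: ["x, y, z"])
    fractional: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        ops = [_parse_op(s) for s in self.symmetry_ops]  # validates
        if not any(op.seitz() == gemmi.Op("x,y,z").seitz() for op in ops):
            raise ValueError("identity operator 'x, y, z' missing from symmetry list")
        if self.fractional is None:
            self.fractional = cart_to_frac(self.cell, self.asymmetric_unit.coords)
        else:
            self.fractional = np.asarray(self.fractional, float)
            if self.fractional.shape != (len(self.asymmetric_unit.atoms), 3):
                raise ValueError("fractional coordinate shape mismatch")


# ---------------------------------------------------------------- fractional

def _gemmi_cell(cell: CrystalCell) -> gemmi.UnitCell:
    return gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)


def frac_to_cart(cell: CrystalCell, frac: np.ndarray) -> np.ndarray:
    """Fractional -> Cartesian (A) using the standard crystallographic basis."""
    m = np.array(_gemmi_cell(cell).orth.mat.tolist())
    return np.atleast_2d(np.asarray(frac, float)) @ m.T


def cart_to_frac(cell: CrystalCell, cart: np.ndarray) -> np.ndarray:
    """Cartesian (A) -> fractional; exact inverse of :func:`frac_to_cart`."""
    m = np.array(_gemmi_cell(cell).frac.mat.tolist())
    return np.atleast_2d(np.asarray(cart, float)) @ m.T


# ----------------------------------------------------------------------- SDF

def _require_rdkit():
    from rdkit import Chem  # deferred: keep import cost out of light paths

    return Chem


def read_sdf(path, energy_field: str = DEFAULT_ENERGY_FIELD) -> Ensemble:
    """Read a multi-record SDF as one ensemble.

    Every record must share the atom count and element sequence (the
    records are conformers of one topology).  The energy is taken from
    the named SDF property when present; an unparseable value issues a
    warning and leaves the energy missing.
    """
    Chem = _require_rdkit()
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    molecule = None
    conformers: List[Conformer] = []
    for rec, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unreadable SDF record {rec} in {path}")
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        conf = mol.GetConformer()
        coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
        if molecule is None:
            atoms = [
                Atom(el, f"{el}{i + 1}", xyz) for i, (el, xyz) in enumerate(zip(elements, coords))
            ]
            bonds = [
                (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), max(1, int(b.GetBondTypeAsDouble())))
                for b in mol.GetBonds()
            ]
            molecule = Molecule(atoms=atoms, bonds=bonds)
        elif elements != molecule.elements:
            raise ValueError(
                f"SDF record {rec} has a different topology "
                f"({len(elements)} atoms vs {len(molecule.atoms)})"
            )
        energy: Optional[float] = None
        if mol.HasProp(energy_field):
            raw = mol.GetProp(energy_field)
            try:
                energy = float(raw)
            except ValueError:
                warnings.warn(f"record {rec}: unparseable energy {raw!r}; treated as missing")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        conformers.append(Conformer(id=name or f"conf{rec}", coords=coords, energy=energy))
    if molecule is None:
        raise ValueError(f"no records in SDF {path}")
    return Ensemble(molecule=molecule, conformers=conformers)


def write_sdf(ensemble: Ensemble, path, energy_field: str = DEFAULT_ENERGY_FIELD) -> None:
    """Write an ensemble as a multi-record SDF with an energy property."""
    Chem = _require_rdkit()
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    for atom in ensemble.molecule.atoms:
        a = Chem.Atom(atom.element)
        a.SetNoImplicit(True)
        mol.AddAtom(a)
    for i, j, order in ensemble.molecule.bonds:
        mol.AddBond(i, j, Chem.BondType.values.get(order, Chem.BondType.SINGLE))
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for c in ensemble.conformers:
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, xyz in enumerate(c.coords):
                conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
            m = Chem.Mol(mol)
            m.RemoveAllConformers()
            m.AddConformer(conf, assignId=True)
            m.SetProp("_Name", c.id)
            if c.energy is not None:
                m.SetProp(energy_field, repr(float(c.energy)))
            writer.write(m)
    finally:
        writer.close()


# ----------------------------------------------------------------------- XYZ

def read_xyz(path) -> Ensemble:
    """Read a (possibly multi-frame) XYZ file as an ensemble.

    Plain whitespace format: atom count, comment, then ``El x y z``
    lines, repeated per frame.  Bonds are perceived on the first frame
    by the covalent-radius criterion (see :func:`perceive_bonds`).
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    frames: List[np.ndarray] = []
    elements: Optional[List[str]] = None
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].split()[0])
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise ValueError(f"truncated XYZ frame at line {pos + 1}")
        els, coords = [], []
        for ln in body:
            parts = ln.split()
            els.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        if elements is None:
            elements = els
        elif els != elements:
            raise ValueError("XYZ frames have inconsistent element sequences")
        frames.append(np.array(coords))
        pos += 2 + n
    if elements is None:
        raise ValueError(f"no frames in XYZ {path}")
    atoms = [Atom(el, f"{el}{i + 1}", xyz) for i, (el, xyz) in enumerate(zip(elements, frames[0]))]
    molecule = Molecule(atoms=atoms, bonds=perceive_bonds(elements, frames[0]))
    confs = [Conformer(id=f"frame{k}", coords=f) for k, f in enumerate(frames)]
    return Ensemble(molecule=molecule, conformers=confs)


def write_xyz(ensemble: Ensemble, path) -> None:
    with open(path, "w") as fh:
        for c in ensemble.conformers:
            fh.write(f"{len(ensemble.molecule.atoms)}\n{c.id}\n")
            for atom, xyz in zip(ensemble.molecule.atoms, c.coords):
                fh.write(f"{atom.element} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


# ----------------------------------------------------------------------- PDB

def read_pdb(path) -> Ensemble:
    """Read a PDB file; each MODEL becomes one conformer."""
    st = gemmi.read_structure(str(path))
    frames: List[np.ndarray] = []
    elements: Optional[List[str]] = None
    labels: List[str] = []
    for model in st:
        els, coords, labs = [], [], []
        for chain in model:
            for res in chain:
                for at in res:
                    els.append(at.element.name)
                    labs.append(at.name)
                    coords.append([at.pos.x, at.pos.y, at.pos.z])
        if elements is None:
            elements, labels = els, labs
        elif els != elements:
            raise ValueError("PDB models have inconsistent atoms")
        frames.append(np.array(coords))
    if elements is None or not frames:
        raise ValueError(f"no models in PDB {path}")
    atoms = [Atom(el, lab, xyz) for el, lab, xyz in zip(elements, labels, frames[0])]
    molecule = Molecule(atoms=atoms, bonds=perceive_bonds(elements, frames[0]))
    confs = [Conformer(id=f"model{k + 1}", coords=f) for k, f in enumerate(frames)]
    return Ensemble(molecule=molecule, conformers=confs)


# ----------------------------------------------------------------------- CIF

def read_cif(path) -> CrystalStructure:
    """Read a small-molecule CIF into a :class:`CrystalStructure`.

    Requires cell parameters and an atom_site loop with fractional
    coordinates; symmetry operators are taken from either the
    ``_symmetry_equiv_pos_as_xyz`` or the
    ``_space_group_symop_operation_xyz`` loop (identity assumed when
    neither is present).  Atom labels are preserved verbatim.
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    def cell_item(tag: str) -> float:
        val = block.find_value(tag)
        if val is None:
            raise ValueError(f"CIF {path} lacks {tag}")
        return float(gemmi.cif.as_number(val))

    cell = CrystalCell(
        a=cell_item("_cell_length_a"),
        b=cell_item("_cell_length_b"),
        c=cell_item("_cell_length_c"),
        alpha=cell_item("_cell_angle_alpha"),
        beta=cell_item("_cell_angle_beta"),
        gamma=cell_item("_cell_angle_gamma"),
        Z=int(gemmi.cif.as_number(block.find_value("_cell_formula_units_Z") or "1")),
        space_group=(block.find_value("_symmetry_space_group_name_H-M") or "P1").strip("'\" "),
    )
    table = block.find(
        "_atom_site_", ["label", "type_symbol", "fract_x", "fract_y", "fract_z"]
    )
    if len(table) == 0:
        raise ValueError(f"CIF {path} lacks an _atom_site_ loop")
    labels, elements, frac = [], [], []
    for row in table:
        labels.append(row[0])
        elements.append(row[1])
        frac.append([gemmi.cif.as_number(row[k]) for k in (2, 3, 4)])
    frac = np.array(frac)
    ops = [val for val in block.find_loop("_symmetry_equiv_pos_as_xyz")]
    if not ops:
        ops = [val for val in block.find_loop("_space_group_symop_operation_xyz")]
    ops = [op.strip("'\" ") for op in ops] or ["x, y, z"]
    cart = frac_to_cart(cell, frac)
    atoms = [Atom(el, lab, xyz) for el, lab, xyz in zip(elements, labels, cart)]
    bonds = perceive_bonds(elements, cart)
    return CrystalStructure(
        cell=cell,
        asymmetric_unit=Molecule(atoms=atoms, bonds=bonds),
        symmetry_ops=ops,
        fractional=frac,
    )


def write_cif(s: CrystalStructure, path, data_name: str = "structure") -> None:
    """Write a minimal CIF (cell, symmetry loop, fractional atom sites)."""
    lines = [
        f"data_{data_name}",
        f"_symmetry_space_group_name_H-M '{s.cell.space_group}'",
        f"_cell_length_a {s.cell.a:.4f}",
        f"_cell_length_b {s.cell.b:.4f}",
        f"_cell_length_c {s.cell.c:.4f}",
        f"_cell_angle_alpha {s.cell.alpha:.4f}",
        f"_cell_angle_beta {s.cell.beta:.4f}",
        f"_cell_angle_gamma {s.cell.gamma:.4f}",
        f"_cell_formula_units_Z {s.cell.Z}",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
    ]
    lines += [f"'{op}'" for op in s.symmetry_ops]
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for atom, f in zip(s.asymmetric_unit.atoms, s.fractional):
        lines.append(f"{atom.label} {atom.element} {f[0]:.6f} {f[1]:.6f} {f[2]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ symmetry

def _parse_op(triplet: str) -> gemmi.Op:
    try:
        return gemmi.Op(triplet.replace(" ", ""))
    except Exception as exc:
        raise ValueError(f"unparseable symmetry operator {triplet!r}") from exc


@dataclass(frozen=True)
class ExpandedAtom:
    """A symmetry image of an asymmetric-unit atom in a packed cluster."""

    atom: Atom  # Cartesian coordinates of the image
    source: int  # index in the asymmetric unit
    op: str  # xyz triplet of the operator applied
    translation: Tuple[int, int, int]  # lattice translation applied

    @property
    def is_identity_image(self) -> bool:
        return self.translation == (0, 0, 0) and _parse_op(self.op).seitz() == gemmi.Op(
            "x,y,z"
        ).seitz()


def expand_symmetry(s: CrystalStructure, shell: int = 1) -> List[ExpandedAtom]:
    """Apply every symmetry operator plus lattice translations in ±shell.

    The identity operator with translation (0,0,0) reproduces the input
    atoms.  No deduplication is performed: the output size is exactly
    ``n_atoms * n_ops * (2*shell + 1)**3``.
    """
    if shell < 0:
        raise ValueError("shell must be >= 0")
    ops = [(t, _parse_op(t)) for t in s.symmetry_ops]
    out: List[ExpandedAtom] = []
    rng = range(-shell, shell + 1)
    for triplet, op in ops:
        for u in rng:
            for v in rng:
                for w in rng:
                    for i, f in enumerate(s.fractional):
                        img = np.array(op.apply_to_xyz(list(map(float, f))))
                        img = img + np.array([u, v, w], float)
                        cart = frac_to_cart(s.cell, img)[0]
                        src = s.asymmetric_unit.atoms[i]
                        out.append(
                            ExpandedAtom(
                                atom=Atom(src.element, src.label, cart),
                                source=i,
                                op=triplet,
                                translation=(u, v, w),
                            )
                        )
    return out


# ------------------------------------------------------------- bond guessing

def perceive_bonds(
    elements: Sequence[str], coords: np.ndarray, slack: float = 0.4
) -> List[Tuple[int, int, int]]:
    """Distance-based bonds: d(i,j) <= r_cov(i) + r_cov(j) + slack (A).

    Needed only for formats without a bond block (XYZ, PDB, CIF); all
    perceived bonds are reported with order 1.
    """
    coords = np.asarray(coords, float)
    radii = np.array([element(el).covalent_radius for el in elements])
    bonds: List[Tuple[int, int, int]] = []
    n = len(elements)
    for i in range(n):
        d = np.linalg.norm(coords[i + 1 :] - coords[i], axis=1)
        cut = radii[i] + radii[i + 1 :] + slack
        for off in np.nonzero((d <= cut) & (d > 1e-4))[0]:
            bonds.append((i, i + 1 + int(off), 1))
    return bonds
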