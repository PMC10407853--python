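"""Geometry primitives against independent oracles."""

import numpy as np
import pytest

from conftest import random_rotation
from foldmimic.geomcore import (
    dihedral,
    hbond_geometry,
    hbond_ring_size,
    lsq_plane_max_deviation,
    pi_stack_geometry,
    superpose,
)
from foldmimic.structio import Atom, Molecule


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0)

    def test_planar_trans_is_180(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(180.0)

    def test_matches_rdkit_on_random_quadruples(self):
        """Cross-library oracle: RDKit's dihedral on the same points."""
        from rdkit import Chem
        from rdkit.Chem import rdMolTransforms
        from rdkit.Geometry import Point3D

        rng = np.random.default_rng(11)
        n = 0
        while n < 100:
            pts = rng.uniform(-5, 5, (4, 3))
            try:
                ours = dihedral(*pts)
            except ValueError:
                continue
            mol = Chem.RWMol()
            for _ in range(4):
                mol.AddAtom(Chem.Atom(6))
            conf = Chem.Conformer(4)
            for i, p in enumerate(pts):
                conf.SetAtomPosition(i, Point3D(*p))
            mol.AddConformer(conf)
            ref = rdMolTransforms.GetDihedralDeg(mol.GetConformer(), 0, 1, 2, 3)
            diff = abs(ours - ref) % 360.0
            assert min(diff, 360.0 - diff) < 1e-6
            n += 1

    def test_sign_flips_under_mirror(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-2, 2, (4, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        d = dihedral(*pts)
        if abs(abs(d) - 180.0) > 1e-9:  # 180 is its own mirror
            assert dihedral(*mirrored) == pytest.approx(-d)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestLsqPlane:
    def test_coplanar_points(self):
        pts = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        _, dev, _ = lsq_plane_max_deviation(pts)
        assert dev < 1e-12

    def test_square_plus_apex(self):
        # centroid sits at h/5; apex deviates 4h/5, base points h/5
        h = 1.7
        pts = np.array(
            [[1, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0], [0, 0, h]], dtype=float
        )
        _, dev, idx = lsq_plane_max_deviation(pts)
        assert idx == 4
        assert dev == pytest.approx(4 * h / 5)

    def test_matches_scipy_minimization(self):
        """Oracle: direct minimization of squared distances over the normal."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = rng.uniform(-3, 3, (10, 3))
            centered = pts - pts.mean(axis=0)

            def cost(angles):
                t, p = angles
                n = np.array(
                    [np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)]
                )
                return np.sum((centered @ n) ** 2)

            best = min(
                (
                    minimize(cost, x0, method="Nelder-Mead")
                    for x0 in rng.uniform(0, np.pi, (8, 2))
                ),
                key=lambda r: r.fun,
            )
            normal, _, _ = lsq_plane_max_deviation(pts)
            assert np.sum((centered @ normal) ** 2) == pytest.approx(best.fun, abs=1e-6)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            lsq_plane_max_deviation([[0, 0, 0], [1, 0, 0], [2, 0, 0]])


def _quaternion_rmsd(X, Y):
    """Horn's quaternion-eigenvalue method: independent of Kabsch/SVD."""
    X0 = X - X.mean(axis=0)
    Y0 = Y - Y.mean(axis=0)
    M = X0.T @ Y0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e = np.sum(X0**2) + np.sum(Y0**2) - 2.0 * lam
    return np.sqrt(max(e, 0.0) / len(X))


class TestSuperpose:
    def test_rigid_copy_gives_zero_rmsd(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-4, 4, (12, 3))
        R = random_rotation(rng)
        Y = X @ R.T + np.array([1.0, -2.0, 0.5])
        res = superpose(X, Y)
        assert res.rmsd < 1e-9
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_identity_on_identical_sets(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        res = superpose(X, X)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(res.translation, 0.0, atol=1e-10)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(4, 20)
            X = rng.uniform(-5, 5, (n, 3))
            Y = rng.uniform(-5, 5, (n, 3))
            assert superpose(X, Y).rmsd == pytest.approx(_quaternion_rmsd(X, Y), abs=1e-8)

    def test_rmsd_invariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(-3, 3, (10, 3))
        Y = rng.uniform(-3, 3, (10, 3))
        base = superpose(X, Y).rmsd
        R = random_rotation(rng)
        t = rng.uniform(-9, 9, 3)
        moved = superpose(X @ R.T + t, Y @ R.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    def test_reflection_not_allowed(self):
        # chiral set vs its mirror: proper rotation cannot reach rmsd 0
        rng = np.random.default_rng(9)
        X = rng.uniform(-3, 3, (8, 3))
        Y = X * np.array([1.0, 1.0, -1.0])
        assert superpose(X, Y).rmsd > 0.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestHBondGeometry:
    def test_linear_arrangement(self):
        g = hbond_geometry([0, 0, 0], [1, 0, 0], [3, 0, 0])
        assert g.d_da == pytest.approx(3.0)
        assert g.d_ha == pytest.approx(2.0)
        assert g.angle_dha == pytest.approx(180.0)

    def test_right_angle_at_h(self):
        g = hbond_geometry([0, 1, 0], [0, 0, 0], [2, 0, 0])
        assert g.angle_dha == pytest.approx(90.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            hbond_geometry([0, 0, 0], [0, 0, 0], [1, 1, 1])


def _chain_molecule(n_heavy: int) -> Molecule:
    """A-C-C-...-D chain with one H on the last heavy atom."""
    atoms = [Atom("O", "A", np.array([0.0, 0.0, 0.0]))]
    atoms += [
        Atom("C", f"C{i}", np.array([float(i), 0.3 * (i % 2), 0.0]))
        for i in range(1, n_heavy - 1)
    ]
    atoms.append(Atom("N", "D", np.array([float(n_heavy - 1), 0.0, 0.0])))
    atoms.append(Atom("H", "HD", np.array([float(n_heavy - 1), 1.0, 0.0])))
    bonds = [(i, i + 1, 1) for i in range(n_heavy)]
    return Molecule(atoms=atoms, bonds=bonds)


class TestHBondRingSize:
    def test_beta_turn_c10_chain(self):
        # 9 heavy atoms A..D plus H -> 10-membered pseudo-cycle
        m = _chain_molecule(9)
        assert hbond_ring_size(m, donor_h=9, acceptor=0) == 10

    def test_minimal_cycle(self):
        m = Molecule(
            atoms=[
                Atom("N", "D", np.zeros(3)),
                Atom("O", "A", np.array([1.3, 0.0, 0.0])),
                Atom("H", "H", np.array([0.0, 1.0, 0.0])),
            ],
            bonds=[(0, 1, 1), (0, 2, 1)],
        )
        assert hbond_ring_size(m, donor_h=2, acceptor=1) == 3

    def test_bond_order_independence(self):
        m = _chain_molecule(9)
        shuffled = Molecule(atoms=m.atoms, bonds=list(reversed(m.bonds)))
        assert hbond_ring_size(m, 9, 0) == hbond_ring_size(shuffled, 9, 0)

    def test_disconnected_acceptor_rejected(self):
        m = Molecule(
            atoms=[
                Atom("N", "D", np.zeros(3)),
                Atom("H", "H", np.array([0, 1.0, 0])),
                Atom("O", "A", np.array([5.0, 0, 0])),
            ],
            bonds=[(0, 1, 1)],
        )
        with pytest.raises(ValueError):
            hbond_ring_size(m, donor_h=1, acceptor=2)


class TestPiStack:
    @staticmethod
    def _hexagon(radius=1.4):
        ang = np.linspace(0, 2 * np.pi, 7)[:-1]
        return np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)

    def test_parallel_offset_rings(self):
        a = self._hexagon()
        b = a + np.array([0.0, 0.0, 3.5])
        dist, angle = pi_stack_geometry(a, b)
        assert dist == pytest.approx(3.5)
        assert angle == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_rings_shared_centroid(self):
        a = self._hexagon()
        b = a @ np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]]).T  # rotate 90 about x
        dist, angle = pi_stack_geometry(a, b)
        assert dist == pytest.approx(0.0, abs=1e-12)
        assert angle == pytest.approx(90.0)
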