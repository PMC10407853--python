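"""Motif classifiers, H-bond patterns and ensemble summaries."""

import dataclasses

import numpy as np
import pytest

from conftest import random_rotation
from foldmimic.mimicry import (
    AnchorSet,
    MotifCriteria,
    classify_310,
    classify_alpha,
    classify_beta,
    detect_hbond_patterns,
    filter_energy_window,
    label_conformer,
    summarize,
)
from foldmimic.structio import Atom, Conformer, Ensemble, Molecule
from foldmimic.synthetic import PlantSpec, gen_ensemble
from foldmimic.turnfit import ideal_helix


def _bare_ensemble(energies):
    mol = Molecule(atoms=[Atom("C", "C1", np.zeros(3))])
    confs = [
        Conformer(id=f"c{i}", coords=np.zeros((1, 3)), energy=e)
        for i, e in enumerate(energies)
    ]
    return Ensemble(molecule=mol, conformers=confs)


class TestEnergyWindow:
    def test_boundary_inclusive(self):
        ens = filter_energy_window(_bare_ensemble([0.0, 5.0, 9.9, 10.0, 10.1]), 10.0)
        assert [c.id for c in ens.conformers] == ["c0", "c1", "c2", "c3"]

    def test_zero_window_keeps_minima(self):
        ens = filter_energy_window(_bare_ensemble([3.0, 1.0, 1.0, 2.0]), 0.0)
        assert [c.id for c in ens.conformers] == ["c1", "c2"]

    def test_matches_linear_scan_on_random_energies(self):
        rng = np.random.default_rng(12)
        energies = list(rng.uniform(-20, 30, 500))
        window = 10.0
        kept = {c.id for c in filter_energy_window(_bare_ensemble(energies), window).conformers}
        e_min = min(energies)
        oracle = {f"c{i}" for i, e in enumerate(energies) if e - e_min <= window}
        assert kept == oracle

    def test_missing_energy_rejected(self):
        ens = _bare_ensemble([0.0, 1.0])
        ens.conformers[1].energy = None
        with pytest.raises(ValueError, match="without energy"):
            filter_energy_window(ens, 10.0)


def _marker_conformer(distances):
    """Three anchor atoms realizing the given pairwise distance triple."""
    d01, d02, d12 = distances
    x2 = (d01**2 + d02**2 - d12**2) / (2 * d01)
    y2 = np.sqrt(max(d02**2 - x2**2, 0.0))
    coords = np.array([[0.0, 0.0, 0.0], [d01, 0.0, 0.0], [x2, y2, 0.0]])
    return Conformer(id="m", coords=coords)


MARKER_ANCHORS = AnchorSet(helix=(0, 1, 2), three10=(0, 1, 2))


class TestClassifyAlpha:
    def test_exact_references_pass(self, criteria):
        c = _marker_conformer(criteria.helix_ref)
        ok, measured = classify_alpha(c, MARKER_ANCHORS, criteria)
        assert ok
        assert measured == pytest.approx(criteria.helix_ref)

    def test_single_violation_fails(self, criteria):
        ref = criteria.helix_ref
        c = _marker_conformer((ref[0], ref[1], ref[2] + 2 * criteria.helix_tol))
        assert not classify_alpha(c, MARKER_ANCHORS, criteria)[0]

    def test_missing_anchors_rejected(self, criteria):
        with pytest.raises(ValueError):
            classify_alpha(_marker_conformer((6, 10, 6)), AnchorSet(), criteria)

    def test_acceptance_fraction_nonincreasing_in_noise(self, criteria):
        rng = np.random.default_rng(5)
        base = _marker_conformer(criteria.helix_ref).coords
        fracs = []
        for sigma in (0.0, 0.25, 0.5, 0.75, 1.0):
            hits = sum(
                classify_alpha(
                    Conformer(id="x", coords=base + rng.normal(0, sigma, base.shape)),
                    MARKER_ANCHORS,
                    criteria,
                )[0]
                for _ in range(200)
            )
            fracs.append(hits / 200)
        # allow small Monte-Carlo wiggle on the monotone trend
        assert all(b <= a + 0.05 for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] == 1.0


class TestClassify310:
    def test_template_distances_pass(self, criteria):
        c = _marker_conformer(criteria.three10_ref)
        assert classify_310(c, MARKER_ANCHORS, criteria)[0]

    def test_alpha_helix_anchors_fail(self, criteria):
        cb = ideal_helix("alpha", 8).CB
        c = Conformer(id="a", coords=cb[[0, 2, 4]])
        assert not classify_310(c, MARKER_ANCHORS, criteria)[0]

    def test_missing_anchor_rejected(self, criteria):
        with pytest.raises(ValueError):
            classify_310(_marker_conformer((6, 9, 6)), AnchorSet(helix=(0, 1, 2)), criteria)


def _quartet_conformer(d_alpha, torsion_deg):
    """Four chain atoms with a controlled end-to-end distance and torsion."""
    from foldmimic.turnfit import _nerf

    p1 = np.array([0.0, 0.0, 0.0])
    p2 = np.array([1.5, 0.0, 0.0])
    p3 = p2 + np.array([0.8, 1.3, 0.0])
    # direction of the last bond fixes the torsion; its length tunes d_alpha
    u = _nerf(p1, p2, p3, 1.0, 115.0, torsion_deg) - p3
    a = p3 - p1
    au = float(a @ u)
    length = -au + np.sqrt(au**2 - a @ a + d_alpha**2)
    p4 = p3 + length * u
    return Conformer(id="q", coords=np.stack([p1, p2, p3, p4]))


QUARTET_ANCHORS = AnchorSet(turn_quartet=(0, 1, 2, 3), d_alpha_pair=(0, 3))


class TestClassifyBeta:
    def test_compact_low_torsion_passes(self, criteria):
        c = _quartet_conformer(5.5, 20.0)
        ok, d_alpha, beta, _ = classify_beta(c, QUARTET_ANCHORS, criteria)
        assert ok
        assert d_alpha == pytest.approx(5.5)

    def test_distance_violation_fails(self, criteria):
        assert not classify_beta(_quartet_conformer(7.5, 20.0), QUARTET_ANCHORS, criteria)[0]

    def test_absolute_value_of_torsion(self, criteria):
        # -75 deg fails |beta| < 60 even though -75 < 60
        ok, _, beta, _ = classify_beta(_quartet_conformer(5.5, -75.0), QUARTET_ANCHORS, criteria)
        assert beta == pytest.approx(-75.0, abs=1.0)
        assert not ok
        assert classify_beta(_quartet_conformer(5.5, -20.0), QUARTET_ANCHORS, criteria)[0]

    def test_missing_anchors_rejected(self, criteria):
        with pytest.raises(ValueError):
            classify_beta(_quartet_conformer(5.0, 0.0), AnchorSet(turn_quartet=(0, 1, 2, 3)),
                          criteria)


class TestHBondPatterns:
    @pytest.fixture()
    def planted(self, mixed_ensemble):
        ens, anchors, labels = mixed_ensemble
        return ens, anchors, labels

    def test_beta_conformers_have_c10(self, planted, criteria):
        ens, anchors, labels = planted
        for c, lab in zip(ens.conformers, labels):
            pat = detect_hbond_patterns(c, anchors, criteria, ens.molecule)
            assert pat["c10"].present == ("beta" in lab)
            if pat["c10"].present:
                assert pat["c10"].ring_size == 10
                assert pat["c10"].geometry.d_ha == pytest.approx(1.97, abs=0.01)
                assert pat["c10"].geometry.angle_dha == pytest.approx(147.0, abs=0.5)

    def test_alpha_conformers_have_double_gamma(self, planted, criteria):
        ens, anchors, labels = planted
        for c, lab in zip(ens.conformers, labels):
            pat = detect_hbond_patterns(c, anchors, criteria, ens.molecule)
            both = pat["gamma_nha"].present and pat["gamma_nhb"].present
            assert both == ("alpha" in lab)
            if pat["gamma_nha"].present:
                assert pat["gamma_nha"].ring_size == 7

    def test_long_contact_absent(self, criteria):
        mol = Molecule(
            atoms=[
                Atom("N", "N", np.array([1.0, 0.0, 0.0])),
                Atom("H", "H", np.zeros(3)),
                Atom("O", "O", np.array([-3.5, 0.0, 0.0])),
            ],
            bonds=[(0, 1, 1), (1, 2, 1)],  # second bond only to keep the graph connected
        )
        anchors = AnchorSet(nhb=(0, 1), nhb_acceptors=(2,))
        c = Conformer(id="x", coords=mol.coords)
        pat = detect_hbond_patterns(c, anchors, criteria, mol)
        assert not pat["c10"].present and not pat["gamma_nhb"].present

    def test_donor_without_hydrogen_rejected(self, criteria):
        mol = Molecule(
            atoms=[Atom("N", "N", np.zeros(3)), Atom("C", "C", np.array([1.0, 0, 0]))],
            bonds=[(0, 1, 1)],
        )
        anchors = AnchorSet(nhb=(0, 1), nhb_acceptors=())
        with pytest.raises(ValueError):
            detect_hbond_patterns(Conformer(id="x", coords=mol.coords), anchors, criteria, mol)


class TestSummarize:
    def test_counting_and_global_min(self, criteria):
        ens, anchors, _ = gen_ensemble(
            PlantSpec(n=10, f_alpha=0.5, f_beta=0.5, global_min="alpha", seed=1)
        )
        s = summarize(ens, anchors, criteria, compound="toy")
        assert (s.pct_beta, s.pct_alpha, s.pct_310) == (50, 50, 0)
        assert s.global_minimum == "alpha-helix"

    def test_all_unlabeled(self, criteria):
        ens, anchors, _ = gen_ensemble(PlantSpec(n=8, seed=2))
        s = summarize(ens, anchors, criteria)
        assert (s.pct_beta, s.pct_alpha, s.pct_310) == (0, 0, 0)
        assert s.global_minimum == "n.d."

    def test_energy_tie_with_conflicting_labels_is_nd(self, criteria):
        ens, anchors, labels = gen_ensemble(
            PlantSpec(n=4, f_alpha=0.5, f_beta=0.5, seed=3)
        )
        ia = next(i for i, l in enumerate(labels) if l == {"alpha"})
        ib = next(i for i, l in enumerate(labels) if l == {"beta"})
        for c in ens.conformers:
            c.energy = 5.0
        ens.conformers[ia].energy = 0.0
        ens.conformers[ib].energy = 0.0
        assert summarize(ens, anchors, criteria).global_minimum == "n.d."

    def test_percentages_permutation_invariant(self, criteria, mixed_ensemble):
        ens, anchors, _ = mixed_ensemble
        s1 = summarize(ens, anchors, criteria)
        rng = np.random.default_rng(0)
        shuffled = Ensemble(
            molecule=ens.molecule,
            conformers=[ens.conformers[i] for i in rng.permutation(len(ens))],
        )
        s2 = summarize(shuffled, anchors, criteria)
        assert (s1.pct_beta, s1.pct_alpha, s1.pct_310) == (s2.pct_beta, s2.pct_alpha, s2.pct_310)


class TestInvariances:
    def test_flags_invariant_under_rigid_motion(self, criteria, mixed_ensemble):
        ens, anchors, _ = mixed_ensemble
        rng = np.random.default_rng(77)
        R, t = random_rotation(rng), rng.uniform(-20, 20, 3)
        for c in ens.conformers[:10]:
            moved = Conformer(id=c.id, coords=c.coords @ R.T + t, energy=c.energy)
            a = label_conformer(c, anchors, criteria, ens.molecule)
            b = label_conformer(moved, anchors, criteria, ens.molecule)
            assert a.flags == b.flags

    def test_alpha_percentage_monotone_in_tolerance(self, criteria):
        ens, anchors, _ = gen_ensemble(PlantSpec(n=60, f_alpha=0.6, sigma=0.4, seed=13))
        pcts = []
        for tol in (1.2, 1.0, 0.7, 0.4, 0.2):
            crit = dataclasses.replace(criteria, helix_tol=tol)
            pcts.append(summarize(ens, anchors, crit).pct_alpha)
        assert all(b <= a for a, b in zip(pcts, pcts[1:]))

    def test_empty_ensemble_rejected(self, criteria):
        ens, anchors, _ = gen_ensemble(PlantSpec(n=1, seed=0))
        with pytest.raises(ValueError):
            Ensemble(molecule=ens.molecule, conformers=[])
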