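"""Charge assignment, dot surfaces, and the screened-Coulomb potential."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hkmtkit import defaults, electrostatics as el
from hkmtkit import synthetic_data as synth
from hkmtkit.structure_io import Atom, Chain, Residue, Structure


def _free_arginine() -> Structure:
    res = Residue("ARG", 1, chain_id="A")
    coords = {
        "N": (0, 0, 0), "CA": (1.45, 0, 0), "C": (2.2, 1.3, 0), "O": (1.6, 2.35, 0),
        "OXT": (3.45, 1.3, 0), "CB": (2.1, -1.2, 0), "CZ": (4.5, -3.0, 0),
        "NE": (3.6, -2.1, 0), "NH1": (5.8, -2.8, 0), "NH2": (4.1, -4.25, 0),
    }
    for i, (name, pos) in enumerate(coords.items()):
        elem = name[0] if name[0] in "NOC" else "C"
        res.add(Atom(i + 1, name, elem, "", np.array(pos, dtype=float)))
    return Structure(id="arg", chains=[Chain(id="A", residues=[res])])


class TestAssignCharges:
    def test_free_arginine_net_charge(self):
        sites, report = el.assign_charges(_free_arginine())
        # guanidinium +1, N-terminus +1, C-terminus -1
        assert report["net_charge"] == pytest.approx(1.0)
        assert report["n_sites"] == 3

    def test_gly_decapeptide_only_termini(self):
        s = synth.make_helix(10)  # poly-Ala backbone, no charged side chains
        sites, report = el.assign_charges(s)
        assert report["n_sites"] == 2
        assert report["net_charge"] == pytest.approx(0.0)

    def test_net_charge_matches_residue_tally(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        s = synth.make_helix(60, sequence=seq)
        # helix residues carry backbone only, so side-chain sites are
        # skipped with a warning; add side-chain group atoms for charged ones
        serial = 1000
        for res in s.iter_residues():
            groups = {"ARG": ["CZ"], "LYS": ["NZ"], "ASP": ["OD1", "OD2"],
                      "GLU": ["OE1", "OE2"]}.get(res.name, [])
            for name in groups:
                res.add(Atom(serial, name, name[0], "",
                             res.atom("CA").coords + np.array([1.0, 1.0, 1.0])))
                serial += 1
        sites, report = el.assign_charges(s)
        expected = (seq.count("R") + seq.count("K")
                    - seq.count("D") - seq.count("E"))   # termini cancel
        assert report["net_charge"] == pytest.approx(expected)

    def test_missing_group_atoms_skipped_with_warning(self):
        s = synth.make_helix(5, sequence="ADAAA")  # Asp without side chain
        with pytest.warns(UserWarning, match="skipped"):
            sites, report = el.assign_charges(s)
        assert any("ASP" in lbl for lbl in report["skipped"])


class TestDotSurface:
    def test_single_atom_sphere_count_and_radius(self):
        res = Residue("UNL", 1, chain_id="A")
        res.add(Atom(1, "C1", "C", "", np.zeros(3), is_hetero=True))
        s = Structure(id="one", chains=[Chain(id="A", residues=[res])])
        points, owners = el.dot_surface(s, probe=1.4, density=1.0)
        r = defaults.VDW_RADII["C"] + 1.4
        np.testing.assert_allclose(np.linalg.norm(points, axis=1), r, atol=1e-9)
        expected = 4.0 * math.pi * r * r
        assert len(points) == pytest.approx(expected, rel=0.02)

    def test_coincident_atoms_share_surface(self):
        res = Residue("UNL", 1, chain_id="A")
        res.add(Atom(1, "C1", "C", "", np.zeros(3), is_hetero=True))
        res.add(Atom(2, "C2", "C", "", np.zeros(3), is_hetero=True))
        s = Structure(id="two", chains=[Chain(id="A", residues=[res])])
        points, _ = el.dot_surface(s)
        r = defaults.VDW_RADII["C"] + defaults.PROBE_RADIUS
        np.testing.assert_allclose(np.linalg.norm(points, axis=1), r, atol=1e-9)

    def test_buried_atom_contributes_no_dots(self):
        res = Residue("UNL", 1, chain_id="A")
        res.add(Atom(1, "C0", "C", "", np.zeros(3), is_hetero=True))
        # octahedral cage of large spheres burying the center atom
        for i, axis in enumerate(np.vstack([np.eye(3), -np.eye(3)])):
            res.add(Atom(2 + i, f"S{i}", "S", "", 1.8 * axis, is_hetero=True))
        s = Structure(id="cage", chains=[Chain(id="A", residues=[res])])
        _, owners = el.dot_surface(s)
        assert 0 not in set(owners)          # center atom fully buried

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            el.dot_surface(Structure(id="empty"))


class TestComputePotential:
    def test_unit_charge_at_one_angstrom(self):
        pm = el.compute_potential(np.array([[1.0, 0.0, 0.0]]),
                                  [(np.zeros(3), 1.0)], dielectric=1.0, kappa=0.0)
        assert pm.potential[0] == pytest.approx(332.0637, abs=1e-9)

    def test_oracle_agreement_at_random_points(self, rng):
        sites, oracle = synth.make_charge_cloud([1.0, -2.0, 0.5, 1.5], seed=5)
        pts = rng.uniform(-8, 8, size=(100, 3))
        for eps, kappa in ((1.0, 0.0), (80.0, 0.1)):
            pm = el.compute_potential(pts, sites, dielectric=eps, kappa=kappa)
            expected = np.array([oracle(p, eps=eps, kappa=kappa) for p in pts])
            np.testing.assert_allclose(pm.potential, expected, atol=1e-9)

    def test_dipole_midplane_is_zero(self):
        sites = [(np.array([0.0, 0.0, 1.0]), 1.0), (np.array([0.0, 0.0, -1.0]), -1.0)]
        pts = np.array([[1.0, 2.0, 0.0], [-3.0, 0.4, 0.0], [0.1, 0.0, 0.0]])
        pm = el.compute_potential(pts, sites, dielectric=1.0)
        np.testing.assert_allclose(pm.potential, 0.0, atol=1e-9)

    def test_linear_in_charges(self, rng):
        pts = rng.uniform(-5, 5, size=(20, 3))
        pos = rng.uniform(-2, 2, size=(6, 3))
        q = rng.uniform(-1, 1, size=6)
        split = rng.uniform(0, 1, size=6)
        full = el.compute_potential(pts, list(zip(pos, q)), dielectric=2.0)
        part1 = el.compute_potential(pts, list(zip(pos, q * split)), dielectric=2.0)
        part2 = el.compute_potential(pts, list(zip(pos, q * (1 - split))), dielectric=2.0)
        np.testing.assert_allclose(full.potential, part1.potential + part2.potential,
                                   atol=1e-9)

    def test_dielectric_scaling_and_unscreened_limit(self):
        pts = np.array([[2.0, 1.0, 0.0]])
        sites = [(np.zeros(3), 1.0)]
        phi_1 = el.compute_potential(pts, sites, dielectric=1.0).potential[0]
        phi_2 = el.compute_potential(pts, sites, dielectric=2.0).potential[0]
        assert phi_2 == pytest.approx(phi_1 / 2.0)
        r = np.linalg.norm(pts[0])
        assert phi_1 == pytest.approx(332.0637 / r)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(-5, 5, size=(15, 3))
        pos = rng.uniform(-2, 2, size=(4, 3))
        q = rng.uniform(-1, 1, size=4)
        rot = synth.random_rotation(rng)
        shift = rng.uniform(-10, 10, size=3)
        before = el.compute_potential(pts, list(zip(pos, q)))
        after = el.compute_potential(pts @ rot.T + shift,
                                     list(zip(pos @ rot.T + shift, q)))
        np.testing.assert_allclose(before.potential, after.potential, atol=1e-9)

    def test_coincident_point_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            pm = el.compute_potential(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
                                      [(np.zeros(3), 1.0)], dielectric=1.0)
        assert pm.potential[0] == 0.0
        assert pm.potential[1] == pytest.approx(332.0637)

    def test_clamp_applied_at_five(self):
        pm = el.compute_potential(np.array([[0.2, 0.0, 0.0]]),
                                  [(np.zeros(3), -1.0)], dielectric=80.0)
        assert pm.potential[0] < -5.0
        assert pm.clamped[0] == -5.0


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=1, max_size=50))
def test_clamp_idempotent(values):
    arr = np.array(values)
    once = el.clamp_potential(arr)
    twice = el.clamp_potential(once)
    np.testing.assert_array_equal(once, twice)
    assert np.all(np.abs(once) <= defaults.CLAMP)


class TestGrooveScore:
    def test_all_zero_charges_score_zero(self, rng):
        pts = rng.uniform(-3, 3, size=(50, 3))
        pmap = el.PotentialMap(points=pts, potential=np.zeros(50),
                               clamped=np.zeros(50), dielectric=80.0,
                               kappa=0.0, clamp=5.0)
        res = Residue("ALA", 1, chain_id="P")
        res.add(Atom(1, "CA", "C", "", np.zeros(3)))
        score = el.groove_score(pmap, res.atoms, patch_cut=10.0)
        assert score.mean_potential == 0.0
        assert score.fraction_negative == 0.0

    def test_aspartate_lined_groove_is_electronegative(self):
        """Four planted carboxylate charges around a groove make the patch
        mean negative and nearly every patch point negative."""
        groove_atoms = []
        res = Residue("UNL", 1, chain_id="A")
        rng = np.random.default_rng(0)
        for i in range(40):  # a crude U-shaped groove of carbon atoms
            angle = math.pi * i / 39
            pos = np.array([6.0 * math.cos(angle), 6.0 * math.sin(angle), 0.0])
            res.add(Atom(i + 1, f"C{i}", "C", "", pos, is_hetero=True))
        s = Structure(id="groove", chains=[Chain(id="A", residues=[res])])
        points, _ = el.dot_surface(s, density=0.5)
        charges = [(np.array([4.0 * math.cos(a), 4.0 * math.sin(a), 0.0]), -1.0)
                   for a in (0.4, 1.2, 2.0, 2.8)]
        pmap = el.compute_potential(points, charges, dielectric=4.0)
        pep = Residue("ALA", 1, chain_id="P")
        pep.add(Atom(999, "CA", "C", "", np.array([0.0, 4.0, 0.0])))
        score = el.groove_score(pmap, pep.atoms, patch_cut=5.0)
        assert score.mean_potential < 0
        assert score.fraction_negative > 0.9

    def test_empty_patch_rejected(self, rng):
        pmap = el.PotentialMap(points=rng.uniform(-1, 1, size=(10, 3)),
                               potential=np.zeros(10), clamped=np.zeros(10),
                               dielectric=80.0, kappa=0.0, clamp=5.0)
        far = Residue("ALA", 1, chain_id="P")
        far.add(Atom(1, "CA", "C", "", np.array([100.0, 0.0, 0.0])))
        with pytest.raises(ValueError, match="patch"):
            el.groove_score(pmap, far.atoms, patch_cut=2.0)
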