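"""Weighted Kabsch fits, seed search, and the iterative core-finding loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hkmtkit import synthetic_data as synth
from hkmtkit import superposition as sup


def _wrmsd(a, b, rot, trans, w):
    d = sup.apply_transform(a, rot, trans) - b
    return float(np.sqrt(np.sum(w * np.sum(d * d, axis=1)) / np.sum(w)))


class TestKabschFit:
    def test_identity_on_identical_sets(self, rng):
        a = rng.normal(size=(6, 3))
        rot, trans = sup.kabsch_fit(a, a)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(trans, 0, atol=1e-12)

    def test_recovers_exact_rigid_motion(self, rng):
        a = rng.normal(size=(8, 3))
        planted = synth.random_rotation(rng)
        shift = np.array([1.0, 2.0, 3.0])
        b = a @ planted.T + shift
        rot, trans = sup.kabsch_fit(a, b)
        np.testing.assert_allclose(rot, planted, atol=1e-9)
        np.testing.assert_allclose(trans, shift, atol=1e-9)
        assert _wrmsd(a, b, rot, trans, np.ones(8)) < 1e-9

    def test_zero_weight_point_is_ignored(self, rng):
        a = rng.normal(size=(4, 3))
        b = a.copy()
        b[3] += [5.0, 0.0, 0.0]
        rot_w, trans_w = sup.kabsch_fit(a, b, np.array([1.0, 1.0, 1.0, 0.0]))
        rot_3, trans_3 = sup.kabsch_fit(a[:3], b[:3])
        np.testing.assert_allclose(rot_w, rot_3, atol=1e-9)
        np.testing.assert_allclose(trans_w, trans_3, atol=1e-9)

    @pytest.mark.parametrize("n", [1, 2])
    def test_too_few_points(self, rng, n):
        pts = rng.normal(size=(n, 3))
        with pytest.raises(ValueError):
            sup.kabsch_fit(pts, pts)

    def test_degenerate_inputs(self, rng):
        collinear = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            sup.kabsch_fit(collinear, collinear)
        a = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            sup.kabsch_fit(a, a, np.zeros(5))

    def test_rotation_always_proper(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 12))
            a = rng.normal(size=(n, 3))
            b = rng.normal(size=(n, 3))
            w = rng.uniform(0.01, 1.0, size=n)
            rot, _ = sup.kabsch_fit(a, b, w)
            assert abs(np.linalg.det(rot) - 1.0) < 1e-9
            assert np.linalg.norm(rot.T @ rot - np.eye(3)) < 1e-9


class TestWeightFormula:
    def test_value_at_d50_is_inverse_e(self):
        d50 = 0.7
        for mode in ("printed", "inverted"):
            w = sup._weights_from_deviation(np.array([d50]), d50, mode)
            assert w[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_zero_deviation_limits(self):
        dev = np.array([0.0, 1.0])
        assert sup._weights_from_deviation(dev, 0.5, "printed")[0] == 0.0
        assert sup._weights_from_deviation(dev, 0.5, "inverted")[0] == 1.0

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-3, max_value=50.0), min_size=4, max_size=40))
    def test_monotonicity_matches_mode(self, devs):
        dev = np.sort(np.array(devs))
        d50 = sup.lower_median(dev)
        printed = sup._weights_from_deviation(dev, d50, "printed")
        inverted = sup._weights_from_deviation(dev, d50, "inverted")
        assert np.all(np.diff(printed) >= -1e-15)   # grows with deviation
        assert np.all(np.diff(inverted) <= 1e-15)   # shrinks with deviation

    def test_lower_median_even_length(self):
        assert sup.lower_median(np.array([4.0, 1.0, 3.0, 2.0])) == 2.0
        assert sup.lower_median(np.array([5.0, 1.0, 3.0])) == 3.0


class TestFindSeeds:
    def test_identical_helices_top_seed_zero(self):
        a = synth.make_helix(30, sequence="ACDEFGHIKLMNPQRSTVWYACDEFGHIKL")
        b = synth.make_helix(30, sequence="ACDEFGHIKLMNPQRSTVWYACDEFGHIKL")
        seeds = sup.find_seeds(a, b)
        assert seeds[0].seed_rmsd < 1e-9
        assert seeds[0].start_a == 1 and seeds[0].start_b == 1

    def test_mobile_domain_excluded_from_top_seed(self):
        a, b, truth = synth.make_two_domain_pair(core_len=15, mobile_len=15,
                                                 noise_sigma=0.0, seed=5)
        seeds = sup.find_seeds(a, b)
        top = seeds[0]
        assert all(r.seq_number <= 15 for r in top.window_a)
        assert top.seed_rmsd < 1e-6

    def test_too_short_structures_raise(self):
        a = synth.make_helix(14)
        with pytest.raises(ValueError):
            sup.find_seeds(a, synth.make_helix(14))


class TestIterativeSuperpose:
    def test_self_superposition_converges_immediately(self, helix30):
        other = synth.make_helix(30)
        result = sup.superpose(helix30, other)
        assert result.unweighted_rmsd < 1e-9
        assert result.iterations_run <= 2
        np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-6)

    @pytest.mark.parametrize("mode", ["printed", "inverted"])
    def test_noise_free_rigid_pair_exact(self, mode):
        a, b, truth = synth.make_rigid_pair(n_res=25, noise_sigma=0.0, seed=9)
        result = sup.superpose(a, b, weight_mode=mode)
        assert result.unweighted_rmsd < 1e-9
        assert sup.rotation_angle_deg(result.rotation, truth["rotation"]) < 1e-6

    def test_two_domain_core_recovery(self, two_domain):
        a, b, truth = two_domain
        result = sup.superpose(a, b, weight_mode="inverted")
        assert sup.rotation_angle_deg(result.rotation, truth["rotation"]) < 0.5
        assert np.linalg.norm(result.translation - truth["translation"]) < 0.35
        core = truth["core_resnums"]
        is_core = np.array([p[0].residue.seq_number in core for p in result.pairing])
        assert result.weights[~is_core].mean() < result.weights[is_core].mean()
        assert result.iterations_run <= 10
        assert result.weighted_rmsd <= result.unweighted_rmsd + 1e-9

    def test_core_oracle_agreement(self, two_domain):
        """The recovered transform matches a Kabsch fit restricted to the
        planted core residues (the independent oracle)."""
        a, b, truth = two_domain
        result = sup.superpose(a, b)
        core = set(truth["core_resnums"])
        pa = np.stack([p.coords for p, q in result.pairing
                       if p.residue.seq_number in core])
        pb = np.stack([q.coords for p, q in result.pairing
                       if p.residue.seq_number in core])
        rot_core, trans_core = sup.kabsch_fit(pa, pb)
        assert sup.rotation_angle_deg(result.rotation, rot_core) < 0.2
        assert np.linalg.norm(result.translation - trans_core) < 0.15

    def test_forward_and_reverse_are_inverse(self):
        a, b, _ = synth.make_rigid_pair(n_res=20, noise_sigma=0.0, seed=3)
        fwd = sup.superpose(a, b)
        rev = sup.superpose(b, a)
        np.testing.assert_allclose(fwd.rotation @ rev.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(fwd.rotation @ rev.translation + fwd.translation,
                                   0.0, atol=1e-6)
        assert abs(fwd.unweighted_rmsd - rev.unweighted_rmsd) < 1e-6

    def test_trace_recorded_per_iteration(self, two_domain):
        a, b, _ = two_domain
        result = sup.superpose(a, b)
        assert len(result.trace) == result.iterations_run
        assert {"iteration", "rmsd", "d50"} <= set(result.trace[0])

    def test_empty_pairing_rejected(self, helix30):
        with pytest.raises(ValueError):
            sup.iterative_superpose(helix30, helix30, pairing=[])


class TestRmsdBetweenSelections:
    def test_identity_transform_same_selection(self, bridge):
        sel = [a for r in bridge.chain("P").residues for a in r.atoms]
        rmsd = sup.rmsd_between_selections((np.eye(3), np.zeros(3)), sel, sel)
        assert rmsd == 0.0

    def test_single_pair_rmsd_is_distance(self):
        from hkmtkit.structure_io import Atom, Residue
        r1 = Residue("ALA", 1, chain_id="A")
        r2 = Residue("ALA", 2, chain_id="A")
        r1.add(Atom(1, "CA", "C", "", np.zeros(3)))
        r2.add(Atom(2, "CA", "C", "", np.array([2.0, 0.0, 0.0])))
        rmsd = sup.rmsd_between_selections((np.eye(3), np.zeros(3)),
                                           r1.atoms, r2.atoms)
        assert rmsd == pytest.approx(2.0)

    def test_transform_not_refitted_on_selection(self):
        a, b, truth = synth.make_rigid_pair(n_res=20, noise_sigma=0.0, seed=1)
        result = sup.superpose(a, b)
        sel_a = [r.atom("CA") for r in a.chains[0].residues[:3]]
        # displace the B-side selection: RMSD must reflect the shift because
        # the domain transform is reused, not refitted
        sel_b = []
        for r in b.chains[0].residues[:3]:
            atom = r.atom("CA")
            atom = type(atom)(atom.serial, atom.name, atom.element, "",
                              atom.coords + np.array([3.0, 0.0, 0.0]))
            atom.residue = r
            sel_b.append(atom)
        rmsd = sup.rmsd_between_selections(result, sel_a, sel_b)
        assert rmsd == pytest.approx(3.0, abs=1e-6)

    def test_unpairable_selection_names(self, bridge):
        pep = bridge.chain("P").residues[1]
        strand = bridge.chain("I").residues[1]
        with pytest.raises(ValueError):
            sup.rmsd_between_selections((np.eye(3), np.zeros(3)),
                                        [pep.atom("N"), pep.atom("CA")],
                                        [strand.atom("C")])
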