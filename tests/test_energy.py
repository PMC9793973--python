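"""Energy terms and table decomposition.

Closed-form checks for the Lennard-Jones, Coulomb and empirical scoring
terms, a brute-force pair-loop oracle for group interactions, and the
central decomposition-conservation property of the energy tables.
"""

import numpy as np
import pytest

from pocketdesign.energy import (
    EnergyTables,
    ScoringWeights,
    coulomb_energy,
    ff_interaction,
    lj_energy,
    vina_score,
    save_tables,
    load_tables,
)
from conftest import make_atom, direct_system_energy


class TestLennardJones:
    def test_minimum_at_rmin(self):
        a = make_atom(rmin_half=1.9, epsilon=0.2)
        b = make_atom(rmin_half=1.7, epsilon=0.05)
        eps = np.sqrt(0.2 * 0.05)
        assert lj_energy(a, b, 3.6) == pytest.approx(-eps, rel=1e-12)

    def test_root_at_sigma(self):
        a = make_atom(rmin_half=1.9, epsilon=0.2)
        b = make_atom(rmin_half=1.9, epsilon=0.2)
        assert lj_energy(a, b, 3.8 * 2 ** (-1 / 6)) == pytest.approx(0.0, abs=1e-12)

    def test_decays_to_zero_from_below(self):
        a = make_atom(rmin_half=1.9, epsilon=0.2)
        e = lj_energy(a, a, 60.0)
        assert -1e-6 < e < 0.0

    def test_zero_distance_rejected(self):
        a = make_atom()
        with pytest.raises(ValueError):
            lj_energy(a, a, 0.0)


class TestCoulomb:
    def test_unit_charges_at_one_angstrom(self):
        a = make_atom(charge=1.0)
        b = make_atom(charge=1.0)
        assert coulomb_energy(a, b, 1.0) == pytest.approx(332.0636, rel=1e-12)

    def test_opposite_charges_at_two_angstrom(self):
        a = make_atom(charge=1.0)
        b = make_atom(charge=-1.0)
        assert coulomb_energy(a, b, 2.0) == pytest.approx(-166.0318, rel=1e-12)

    def test_zero_charge_is_zero(self):
        assert coulomb_energy(make_atom(charge=0.0), make_atom(charge=0.7), 1.5) == 0.0


class TestFFInteraction:
    def test_two_neutral_atoms_at_rmin(self):
        a = make_atom(rmin_half=1.9, epsilon=0.1, coords=(0, 0, 0))
        b = make_atom(rmin_half=1.9, epsilon=0.1, coords=(3.8, 0, 0))
        assert ff_interaction([a], [b]) == pytest.approx(-0.1, rel=1e-12)

    def test_distant_neutral_groups_negligible(self):
        ga = [make_atom(coords=(0, 0, 0)), make_atom(coords=(1.5, 0, 0))]
        gb = [make_atom(coords=(100.0, 0, 0))]
        assert abs(ff_interaction(ga, gb)) < 1e-6

    def test_matches_brute_force_pair_loop(self):
        """3-atom vs 2-atom groups equal the hand-summed 6-term value."""
        rng = np.random.default_rng(5)
        ga = [
            make_atom(coords=rng.uniform(0, 3, 3), charge=rng.uniform(-0.5, 0.5),
                      rmin_half=rng.uniform(1.5, 2.0), epsilon=rng.uniform(0.05, 0.3))
            for _ in range(3)
        ]
        gb = [
            make_atom(coords=rng.uniform(5, 8, 3), charge=rng.uniform(-0.5, 0.5),
                      rmin_half=rng.uniform(1.5, 2.0), epsilon=rng.uniform(0.05, 0.3))
            for _ in range(2)
        ]
        expected = 0.0
        for a in ga:
            for b in gb:
                r = float(np.linalg.norm(a.coords - b.coords))
                rm = a.lj_rmin_half + b.lj_rmin_half
                eps = np.sqrt(a.lj_epsilon * b.lj_epsilon)
                expected += eps * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
                expected += 332.0636 * a.charge * b.charge / r
        assert ff_interaction(ga, gb) == pytest.approx(expected, rel=1e-12)

    def test_exclusions_and_14_scaling(self):
        from pocketdesign.model import ForceFieldParams

        a = [make_atom(coords=(0, 0, 0), charge=0.3)]
        b = [make_atom(coords=(2.0, 0, 0), charge=-0.4), make_atom(coords=(3.5, 0, 0), charge=0.2)]
        params = ForceFieldParams()
        full = ff_interaction(a, b, params)
        excl = ff_interaction(a, b, params, exclusions={(0, 0): "excluded"})
        only_second = ff_interaction(a, [b[1]], params)
        assert excl == pytest.approx(only_second, rel=1e-12)
        scaled = ff_interaction(a, b, params, exclusions={(0, 0): "scale14"})
        pair0 = full - only_second
        lj0 = ff_interaction(
            [make_atom(coords=(0, 0, 0))], [make_atom(coords=(2.0, 0, 0))], params
        )
        expected = only_second + params.lj_14_scale * lj0 + params.coulomb_14_scale * (pair0 - lj0)
        assert scaled == pytest.approx(expected, rel=1e-10)


class TestVina:
    W1 = ScoringWeights(w_gauss1=1, w_gauss2=1, w_repulsion=1, w_hydrophobic=1, w_hbond=1)

    def _pair(self, d, cls_a="none", cls_b="none"):
        # surface distance d = r - (Ra + Rb), radii 1.9 each
        lig = [make_atom(coords=(0, 0, 0), vdw_radius=1.9, atom_class=cls_a)]
        rec = [make_atom(coords=(d + 3.8, 0, 0), vdw_radius=1.9, atom_class=cls_b)]
        return lig, rec

    def test_contact_distance_terms(self):
        lig, rec = self._pair(0.0)
        g1 = ScoringWeights(w_gauss1=1, w_gauss2=0, w_repulsion=0, w_hydrophobic=0, w_hbond=0)
        g2 = ScoringWeights(w_gauss1=0, w_gauss2=1, w_repulsion=0, w_hydrophobic=0, w_hbond=0)
        rep = ScoringWeights(w_gauss1=0, w_gauss2=0, w_repulsion=1, w_hydrophobic=0, w_hbond=0)
        assert vina_score(lig, rec, g1) == pytest.approx(1.0, rel=1e-12)
        assert vina_score(lig, rec, g2) == pytest.approx(np.exp(-2.25), rel=1e-12)
        assert vina_score(lig, rec, rep) == 0.0

    def test_repulsion_quadratic_inside(self):
        lig, rec = self._pair(-1.0)
        rep = ScoringWeights(w_gauss1=0, w_gauss2=0, w_repulsion=1, w_hydrophobic=0, w_hbond=0)
        assert vina_score(lig, rec, rep) == pytest.approx(1.0, rel=1e-12)

    def test_hydrophobic_ramp_midpoint(self):
        lig, rec = self._pair(1.0, "hydrophobic", "hydrophobic")
        w = ScoringWeights(w_gauss1=0, w_gauss2=0, w_repulsion=0, w_hydrophobic=1, w_hbond=0)
        assert vina_score(lig, rec, w) == pytest.approx(0.5, rel=1e-12)

    def test_hbond_requires_donor_acceptor(self):
        w = ScoringWeights(w_gauss1=0, w_gauss2=0, w_repulsion=0, w_hydrophobic=0, w_hbond=1)
        lig, rec = self._pair(-0.35, "hbond_donor", "hbond_acceptor")
        assert vina_score(lig, rec, w) == pytest.approx(0.5, rel=1e-12)
        lig, rec = self._pair(-0.35, "hbond_donor", "hbond_donor")
        assert vina_score(lig, rec, w) == 0.0

    def test_cutoff_skips_distant_pairs(self):
        lig, rec = self._pair(8.1 - 3.8)  # r = 8.1 > 8 cutoff
        assert vina_score(lig, rec, self.W1) == 0.0

    def test_rigid_motion_invariance(self):
        from pocketdesign.geometry import euler_rotation_matrix

        rng = np.random.default_rng(11)
        lig = [make_atom(coords=rng.uniform(0, 3, 3), atom_class="hydrophobic") for _ in range(3)]
        rec = [make_atom(coords=rng.uniform(2, 6, 3), atom_class="hydrophobic") for _ in range(4)]
        before = vina_score(lig, rec, self.W1)
        rot = euler_rotation_matrix(33.0, -71.0, 145.0)
        shift = np.array([4.0, -2.0, 7.0])
        lig2 = [a.moved_to(rot @ a.coords + shift) for a in lig]
        rec2 = [a.moved_to(rot @ a.coords + shift) for a in rec]
        assert vina_score(lig2, rec2, self.W1) == pytest.approx(before, rel=1e-10)


class TestTables:
    def test_shapes(self, solved_project):
        tables = solved_project._tables
        rset = solved_project._rotamer_set
        n_kept = rset.n_kept
        assert tables.n_rotamers == n_kept
        assert tables.n_poses == solved_project._pose_set.n_kept
        assert set(tables.pair_packing) == {(0, 1)}
        assert tables.pair_packing[(0, 1)].shape == (n_kept[0], n_kept[1])
        for p, m in enumerate(tables.lig_pair_binding):
            assert m.shape == (tables.n_poses, n_kept[p])

    def test_decomposition_conservation_sampled(self, solved_project):
        """Table sums reproduce the directly assembled system energy."""
        tables = solved_project._tables
        pocket = solved_project._pocket
        kept_rots = solved_project._rotamer_set.kept_rotamers()
        kept_poses = solved_project._pose_set.kept_poses()
        rng = np.random.default_rng(0)
        for _ in range(10):
            choice = tuple(int(rng.integers(0, n)) for n in tables.n_rotamers)
            pose_i = int(rng.integers(0, tables.n_poses))
            total, packing, binding = tables.assignment_energy(choice, pose_i)
            d_total, d_packing, d_binding = direct_system_energy(
                pocket,
                [kept_rots[p][r] for p, r in enumerate(choice)],
                kept_poses[pose_i],
                solved_project.params,
                solved_project.weights,
                tables.binding_scale,
            )
            assert total == pytest.approx(d_total, rel=1e-9, abs=1e-9)
            assert packing == pytest.approx(d_packing, rel=1e-9, abs=1e-9)
            assert binding == pytest.approx(d_binding, rel=1e-9, abs=1e-9)

    def test_pair_symmetry_convention(self, solved_project):
        """pair[(p,q)][r,s] is the single stored orientation of a symmetric term."""
        tables = solved_project._tables
        pocket = solved_project._pocket
        kept = solved_project._rotamer_set.kept_rotamers()
        m = tables.pair_packing[(0, 1)]
        r, s = 0, min(1, m.shape[1] - 1)
        swapped = ff_interaction(
            kept[1][s].atoms, kept[0][r].atoms, solved_project.params
        )
        assert m[r, s] == pytest.approx(swapped, rel=1e-12)

    def test_binding_scale_linearity(self, solved_project):
        tables = solved_project._tables
        t1 = EnergyTables(
            self_packing=tables.self_packing,
            pair_packing=tables.pair_packing,
            lig_self_binding=tables.lig_self_binding,
            lig_pair_binding=tables.lig_pair_binding,
            binding_scale=1.0,
        )
        choice = tuple(0 for _ in tables.n_rotamers)
        tot50, pack50, bind50 = tables.assignment_energy(choice, 0)
        tot1, pack1, bind1 = t1.assignment_energy(choice, 0)
        assert pack50 == pack1
        assert bind50 == bind1
        assert tot50 - pack50 == pytest.approx(50.0 * (tot1 - pack1), rel=1e-12)

    def test_workers_bit_identical(self, solved_project):
        """Two worker processes produce byte-identical tables."""
        from pocketdesign.energy import compute_tables

        t2 = compute_tables(
            solved_project._pocket,
            solved_project._rotamer_set,
            solved_project._pose_set,
            params=solved_project.params,
            weights=solved_project.weights,
            binding_scale=solved_project._tables.binding_scale,
            workers=2,
        )
        t1 = solved_project._tables
        for a, b in zip(t1._all_arrays(), t2._all_arrays()):
            assert np.array_equal(a, b)

    def test_roundtrip_serialization(self, solved_project, tmp_path):
        tables = solved_project._tables
        save_tables(tables, tmp_path / "tables")
        again = load_tables(tmp_path / "tables")
        for a, b in zip(tables._all_arrays(), again._all_arrays()):
            assert np.array_equal(a, b)
        assert again.binding_scale == tables.binding_scale

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            EnergyTables(
                self_packing=[np.array([0.0, np.inf])],
                pair_packing={},
                lig_self_binding=np.array([0.0]),
                lig_pair_binding=[np.zeros((1, 2))],
            )
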