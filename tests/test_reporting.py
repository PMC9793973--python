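"""Design output: structure export, ranking criterion, RMSD, reports."""

import copy

import numpy as np
import pytest

from pocketdesign.geometry import euler_rotation_matrix
from pocketdesign.model import read_scaffold
from pocketdesign.reporting import (
    build_report,
    ligand_rmsd,
    pocket_rmsd,
    rank_pair,
    render_report,
    rescore_design,
    write_design_structure,
)
from pocketdesign.solver import Solution


def _solution(binding, total=None, packing=0.0, scale=50.0):
    total = total if total is not None else packing + scale * binding
    return Solution(
        rotamer_choice=(0,),
        pose_choice=0,
        total_energy=total,
        packing_energy=packing,
        binding_energy_raw=binding,
        binding_energy_scaled=binding * scale,
    )


class TestWriteDesignStructure:
    def test_atom_count_is_sum_of_parts(self, solved_project, tmp_path):
        sol = solved_project._solutions[0]
        out = tmp_path / "design.pdb"
        write_design_structure(
            solved_project._pocket, sol, solved_project._rotamer_set,
            solved_project._pose_set, out,
        )
        kept = solved_project._rotamer_set.kept_rotamers()
        expected = (
            solved_project._pocket.fixed_scaffold.n_atoms
            + sum(len(kept[p][r].atoms) for p, r in enumerate(sol.rotamer_choice))
            + len(solved_project.conformers[0].atoms)
        )
        n_lines = sum(
            1 for ln in out.read_text().splitlines() if ln.startswith(("ATOM", "HETATM"))
        )
        assert n_lines == expected
        assert any(ln.startswith("HETATM") for ln in out.read_text().splitlines())

    def test_roundtrip_rescoring(self, solved_project, tmp_path, toy_paths):
        """Re-reading the written PDB reproduces the solution energies.

        The comparison is exact once coordinates are rounded to the 1e-3
        Angstrom precision of the format: rescoring the written file must
        equal recomputing the energies from rounded in-memory coordinates.
        The shallow empirical binding term is insensitive to the rounding
        and must also match the solver's value directly.
        """
        from pocketdesign.energy import (
            ff_interaction,
            vina_score,
            rotamer_scaffold_exclusions,
            _scaffold_label_index,
        )

        sol = solved_project._solutions[0]
        out = tmp_path / "design.pdb"
        write_design_structure(
            solved_project._pocket, sol, solved_project._rotamer_set,
            solved_project._pose_set, out,
        )
        positions = [(p.chain, p.seq_id) for p in solved_project._pocket.positions]
        scale = solved_project._tables.binding_scale
        total, packing, binding = rescore_design(
            out,
            toy_paths["scaffold_params"],
            toy_paths["ligand_params"],
            positions,
            params=solved_project.params,
            weights=solved_project.weights,
            binding_scale=scale,
        )

        # expected values from rounded in-memory coordinates
        pocket = solved_project._pocket
        kept = solved_project._rotamer_set.kept_rotamers()
        rots = [kept[p][r] for p, r in enumerate(sol.rotamer_choice)]
        pose = solved_project._pose_set.kept_poses()[sol.pose_choice]

        def rounded(atoms):
            # decimal formatting mirrors the PDB writer's %.3f exactly
            return [
                a.moved_to([float(f"{x:.3f}") for x in a.coords]) for a in atoms
            ]

        fixed = rounded(pocket.fixed_scaffold.atoms)
        rot_atoms = [rounded(r.atoms) for r in rots]
        lig_atoms = rounded(pose.atoms)
        exp_packing = 0.0
        for p, rot in enumerate(rots):
            labels = _scaffold_label_index(pocket, pocket.position_indices[p])
            excl = rotamer_scaffold_exclusions(rot.aa, [a.name for a in rot.atoms], labels)
            exp_packing += ff_interaction(rot_atoms[p], fixed, solved_project.params, excl)
        for p in range(len(rots)):
            for q in range(p + 1, len(rots)):
                exp_packing += ff_interaction(rot_atoms[p], rot_atoms[q], solved_project.params)
        exp_binding = vina_score(
            lig_atoms, fixed + [a for g in rot_atoms for a in g], solved_project.weights
        )
        # reader backend stores coordinates in float32 (~5e-7 Angstrom),
        # which steep contact terms amplify into the 1e-5 energy range
        assert packing == pytest.approx(exp_packing, abs=1e-4)
        assert binding == pytest.approx(exp_binding, abs=1e-4)
        assert total == pytest.approx(exp_packing + scale * exp_binding, abs=1e-3)
        # the empirical score is shallow: rounding cannot move it appreciably
        assert binding == pytest.approx(sol.binding_energy_raw, abs=1e-2)


class TestRankPair:
    def test_correct_when_stronger_binder_scores_lower(self):
        verdict = rank_pair(_solution(-8.0), _solution(-12.1))
        assert verdict.by_binding == "correct"

    def test_incorrect_when_ordering_reversed(self):
        verdict = rank_pair(_solution(-12.1), _solution(-8.0))
        assert verdict.by_binding == "incorrect"

    def test_tie_is_incorrect_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            verdict = rank_pair(_solution(-5.0), _solution(-5.0))
        assert verdict.by_binding == "incorrect"

    def test_swap_flips_verdict(self):
        a, b = _solution(-8.0), _solution(-12.1)
        assert rank_pair(a, b).by_binding == "correct"
        assert rank_pair(b, a).by_binding == "incorrect"

    def test_total_and_binding_columns_independent(self):
        low = _solution(binding=-10.0, total=5.0)
        high = _solution(binding=-8.0, total=1.0)
        verdict = rank_pair(low, high)
        assert verdict.by_binding == "incorrect"
        assert verdict.by_total == "correct"


class TestPocketRMSD:
    def test_self_is_zero(self, solved_project):
        ref = solved_project.scaffold
        flex = [(p.chain, p.seq_id) for p in solved_project._pocket.positions]
        assert pocket_rmsd(ref, ref, flex) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_is_zero(self, solved_project):
        ref = solved_project.scaffold
        moved = copy.deepcopy(ref)
        rot = euler_rotation_matrix(25.0, 40.0, -60.0)
        shift = np.array([3.0, -1.0, 2.0])
        for res in moved.residues:
            for a in res.atoms:
                a.coords = rot @ a.coords + shift
        flex = [(p.chain, p.seq_id) for p in solved_project._pocket.positions]
        assert pocket_rmsd(ref, moved, flex) < 1e-6

    def test_single_displaced_atom(self, solved_project):
        """One atom displaced by 1 Angstrom among 4 compared atoms: RMSD 0.5."""
        ref = solved_project.scaffold
        moved = copy.deepcopy(ref)
        leu = moved.residues[2]
        assert leu.aa == "LEU"
        sc_names = [a.name for a in leu.sidechain_atoms]
        assert len(sc_names) == 4  # CB CG CD1 CD2
        leu.atom("CD1").coords = leu.atom("CD1").coords + np.array([1.0, 0.0, 0.0])
        assert pocket_rmsd(ref, moved, [("A", 3)]) == pytest.approx(0.5, abs=1e-9)

    def test_invariant_under_joint_rigid_transform(self, solved_project):
        ref = solved_project.scaffold
        moved = copy.deepcopy(ref)
        moved.residues[2].atom("CD1").coords = (
            moved.residues[2].atom("CD1").coords + np.array([0.0, 1.0, 0.0])
        )
        base = pocket_rmsd(ref, moved, [("A", 3)])
        rot = euler_rotation_matrix(-15.0, 75.0, 110.0)
        for res in moved.residues:
            for a in res.atoms:
                a.coords = rot @ a.coords + np.array([-4.0, 2.0, 9.0])
        assert pocket_rmsd(ref, moved, [("A", 3)]) == pytest.approx(base, abs=1e-6)

    def test_name_mismatch_reported(self, solved_project):
        ref = solved_project.scaffold
        moved = copy.deepcopy(ref)
        moved.residues[2].atom("CD1").name = "CD9"
        with pytest.raises(ValueError, match="A3"):
            pocket_rmsd(ref, moved, [("A", 3)])

    def test_ligand_rmsd_rigid_zero(self, solved_project):
        ref = solved_project.scaffold
        lig = solved_project.conformers[0].atoms
        moved = copy.deepcopy(ref)
        lig2 = [a.moved_to(a.coords) for a in lig]
        rot = euler_rotation_matrix(10.0, 20.0, 30.0)
        for res in moved.residues:
            for a in res.atoms:
                a.coords = rot @ a.coords
        for a in lig2:
            a.coords = rot @ a.coords
        assert ligand_rmsd(ref, moved, lig, lig2) < 1e-6


class TestRenderReport:
    def test_byte_identical_rendering(self, solved_project):
        tables = solved_project._tables
        report = build_report(tables, solved_project._solutions,
                              rotamer_set=solved_project._rotamer_set)
        assert render_report(report, "text") == render_report(report, "text")
        assert render_report(report, "html") == render_report(report, "html")

    def test_html_well_formed(self, solved_project):
        from lxml import etree

        report = build_report(solved_project._tables, solved_project._solutions)
        html = render_report(report, "html")
        etree.fromstring(html.split("\n", 1)[1].encode())  # parse past doctype

    def test_breakdown_sums_match_totals(self, solved_project):
        report = build_report(solved_project._tables, solved_project._solutions)
        scale = solved_project._tables.binding_scale
        for sol, terms in zip(report.solutions, report.breakdowns):
            packing = sum(terms["self"].values()) + sum(terms["pair"].values())
            binding = sum(terms["ligand"].values())
            assert packing == pytest.approx(sol.packing_energy, abs=1e-9)
            assert binding == pytest.approx(sol.binding_energy_raw, abs=1e-9)
            assert packing + scale * binding == pytest.approx(sol.total_energy, abs=1e-9)

    def test_unknown_format_rejected(self, solved_project):
        report = build_report(solved_project._tables, solved_project._solutions)
        with pytest.raises(ValueError):
            render_report(report, "pdf")
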