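"""Rotamer building: backbone dihedrals, exact chi placement, vdW pruning."""

import numpy as np
import pytest

from pocketdesign.model import RotamerLibrary, read_scaffold
from pocketdesign.rotamers import (
    backbone_dihedrals,
    build_rotamers,
    build_rotamer_set,
    measure_chis,
    prune_by_scaffold_vdw,
)
from pocketdesign.energy import lj_interaction, rotamer_scaffold_exclusions, _scaffold_label_index, AtomBlock
from pocketdesign.templates import RESIDUE_TEMPLATES


@pytest.fixture(scope="module")
def toy_scaffold(toy_paths):
    return read_scaffold(toy_paths["scaffold"], toy_paths["scaffold_params"])


@pytest.fixture(scope="module")
def toy_params(toy_paths):
    from pocketdesign.model import read_param_table

    return read_param_table(toy_paths["scaffold_params"])


class TestBackboneDihedrals:
    def test_ideal_helix_phi_psi(self, toy_scaffold):
        """The helix fixture is built at (phi, psi) = (-57, -47)."""
        for i in (1, 2, 3, 4):
            phi, psi = backbone_dihedrals(toy_scaffold, i)
            assert phi == pytest.approx(-57.0, abs=2.0)
            assert psi == pytest.approx(-47.0, abs=2.0)

    def test_terminus_rejected(self, toy_scaffold):
        with pytest.raises(ValueError, match="terminus"):
            backbone_dihedrals(toy_scaffold, 0)
        with pytest.raises(ValueError, match="terminus"):
            backbone_dihedrals(toy_scaffold, len(toy_scaffold.residues) - 1)


class TestBuildRotamers:
    def _library(self, aa, chi_sets):
        entries = {(aa, "*", "*"): [(chis, 0.2) for chis in chi_sets]}
        return RotamerLibrary(entries=entries, bin_width=10.0)

    @pytest.mark.parametrize(
        "aa,chis",
        [
            ("SER", (-60.0,)),
            ("LEU", (-60.0, 180.0)),
            ("LEU", (62.5, -171.3)),
            ("PHE", (-65.0, 90.0)),
        ],
    )
    def test_requested_chis_reproduced(self, toy_scaffold, toy_params, aa, chis):
        if aa == "PHE":
            # PHE parameters are not in the default toy table; extend
            from pocketdesign.fixtures import _SIDECHAIN_ROWS, _ELEMENT_PARAMS

            for name, el, q, cls in _SIDECHAIN_ROWS["PHE"]:
                rmin, eps, vdwr = _ELEMENT_PARAMS[el]
                toy_params.scaffold.setdefault(
                    ("PHE", name),
                    {"charge": q, "rmin_half": rmin, "epsilon": eps, "vdw_radius": vdwr, "atom_class": cls},
                )
        lib = self._library(aa, [chis])
        (rot,) = build_rotamers(toy_scaffold, 2, aa, lib, toy_params)
        res = toy_scaffold.residues[2]
        atom_map = {a.name: a.coords for a in res.atoms if a.name in ("N", "CA", "C")}
        all_atoms = [type("A", (), {"name": n, "coords": c})() for n, c in atom_map.items()]
        measured = measure_chis(aa, all_atoms + rot.atoms)
        assert measured == pytest.approx(chis, abs=0.5)
        # construction is exact, not merely within tolerance
        assert measured == pytest.approx(chis, abs=1e-8)

    def test_ala_single_rotamer_no_chis(self, toy_scaffold, toy_params):
        lib = RotamerLibrary(entries={}, bin_width=10.0)
        rots = build_rotamers(toy_scaffold, 2, "ALA", lib, toy_params)
        assert len(rots) == 1
        assert rots[0].chis == ()
        assert [a.name for a in rots[0].atoms] == ["CB"]

    def test_entry_count_and_probs_copied(self, toy_scaffold, toy_params):
        lib = self._library("LEU", [(-60.0, 180.0), (180.0, 60.0), (60.0, 60.0)])
        rots = build_rotamers(toy_scaffold, 2, "LEU", lib, toy_params)
        assert len(rots) == 3
        assert all(r.source_prob == 0.2 for r in rots)

    def test_missing_aa_warns_and_returns_empty(self, toy_scaffold, toy_params):
        lib = RotamerLibrary(entries={("SER", -60.0, -50.0): [((-60.0,), 0.5)]}, bin_width=10.0)
        with pytest.warns(UserWarning, match="no VAL rotamers"):
            assert build_rotamers(toy_scaffold, 2, "VAL", lib, toy_params) == []

    def test_rigid_group_property(self, toy_scaffold, toy_params):
        """Distances between atoms not separated by a chi axis are chi-invariant."""
        lib = self._library("LEU", [(-60.0, 180.0), (55.0, -90.0)])
        r1, r2 = build_rotamers(toy_scaffold, 2, "LEU", lib, toy_params)

        def dmat(rot, names):
            c = {a.name: a.coords for a in rot.atoms}
            pts = np.array([c[n] for n in names])
            return np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))

        # CG/CD1/CD2 are rigid relative to each other under any chi
        rigid = ["CG", "CD1", "CD2"]
        assert np.allclose(dmat(r1, rigid), dmat(r2, rigid), atol=1e-9)
        # bond lengths match the template
        tmpl = {rec[0]: rec[3] for rec in RESIDUE_TEMPLATES["LEU"]}
        coords = {a.name: a.coords for a in r1.atoms}
        coords.update({n: toy_scaffold.residues[2].atom(n).coords for n in ("N", "CA", "C")})
        parents = {rec[0]: rec[2][2] for rec in RESIDUE_TEMPLATES["LEU"]}
        for name, parent in parents.items():
            d = np.linalg.norm(coords[name] - coords[parent])
            assert d == pytest.approx(tmpl[name], abs=1e-3)


class TestPruning:
    def test_pruning_is_pure_threshold_filter(self, solved_project):
        """Kept set equals {rotamer : scaffold LJ < 100} verified independently."""
        rset = solved_project._rotamer_set
        pocket = solved_project._pocket
        params = solved_project.params
        scaffold_block = AtomBlock.from_atoms(pocket.fixed_scaffold.atoms)
        for p, rots in enumerate(rset.rotamers):
            for i, rot in enumerate(rots):
                labels = _scaffold_label_index(pocket, pocket.position_indices[p])
                excl = rotamer_scaffold_exclusions(rot.aa, [a.name for a in rot.atoms], labels)
                # independent brute-force pair loop
                e = 0.0
                for ai, a in enumerate(rot.atoms):
                    for bi, b in enumerate(pocket.fixed_scaffold.atoms):
                        scale = 1.0
                        kind = excl.get((ai, bi))
                        if kind == "excluded":
                            continue
                        if kind == "scale14":
                            scale = params.lj_14_scale
                        r = np.linalg.norm(a.coords - b.coords)
                        rm = a.lj_rmin_half + b.lj_rmin_half
                        eps = np.sqrt(a.lj_epsilon * b.lj_epsilon)
                        e += scale * eps * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
                assert e == pytest.approx(rset.scaffold_vdw[p][i], rel=1e-9)
                assert rset.kept[p][i] == (e < 100.0)

    def test_toy_system_has_pruned_and_kept(self, solved_project):
        rset = solved_project._rotamer_set
        all_vdw = np.concatenate(rset.scaffold_vdw)
        assert (all_vdw >= 100.0).any()
        assert (all_vdw < 100.0).any()

    def test_all_pruned_raises(self, toy_scaffold, toy_params, toy_paths):
        from pocketdesign.pocket import DesignPosition, build_pocket

        # an impossible threshold empties every position
        positions = [DesignPosition(chain="A", seq_id=3, allowed_aas=["LEU"])]
        pocket = build_pocket(toy_scaffold, positions)
        lib = RotamerLibrary(
            entries={("LEU", "*", "*"): [((-60.0, 180.0), 0.5)]}, bin_width=10.0
        )
        rset = build_rotamer_set(pocket, lib, toy_params)
        with pytest.raises(ValueError, match="no viable rotamers"):
            prune_by_scaffold_vdw(rset, pocket, toy_params, threshold=-1e9)
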