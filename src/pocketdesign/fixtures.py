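"""Deterministic toy pocket generator.

Builds chemically naive but geometrically valid design systems — a short
ideal-geometry peptide scaffold, a small rigid ligand placed in the
pocket, bespoke parameter/rotamer tables — so the full pipeline can be
exercised and brute-force-verified without any external data.  Every
output is a plain-text file and byte-identical for a given spec.

Construction guarantees (validated at generation time):

* at least one library rotamer clashes with the scaffold (Lennard-Jones
  >= 100 kcal/mol, exercising the pruning step) — found by scanning chi
  angles for the maximal-clash side chain;
* at least one kept rotamer makes a favourable (negative) empirical
  score contact with the ligand, exercising the binding track;
* the instance is small enough for exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .energy import AtomBlock, lj_interaction, vina_score, rotamer_scaffold_exclusions, _scaffold_label_index
from .geometry import place_atom
from .model import (
    Atom,
    Residue,
    Scaffold,
    read_param_table,
)
from .rotamers import backbone_dihedrals, _build_sidechain
from .templates import CHI_COUNT

__all__ = ["ToySystemSpec", "make_toy_system", "make_known_optimum_instance"]

# ideal backbone internal coordinates (Å / degrees)
_BB = {
    "n_ca": 1.458,
    "ca_c": 1.525,
    "c_n": 1.329,
    "c_o": 1.231,
    "ang_c_n_ca": 121.7,
    "ang_n_ca_c": 111.2,
    "ang_ca_c_n": 116.2,
    "ang_ca_c_o": 120.8,
    "omega": 180.0,
}

_GEOMETRIES = {"helix": (-57.0, -47.0), "strand": (-120.0, 120.0)}


@dataclass
class ToySystemSpec:
    """Parameters of one toy design system (deterministic given seed)."""

    n_pocket_residues: int = 6
    aas: list[str] = field(default_factory=lambda: ["LEU", "SER"])
    ligand_atom_count: int = 4
    seed: int = 0
    geometry: str = "helix"
    n_conformers: int = 1

    def __post_init__(self) -> None:
        if self.n_pocket_residues < 5:
            raise ValueError("need at least 5 residues for interior design positions")
        if not 2 <= self.ligand_atom_count <= 5:
            raise ValueError("ligand_atom_count must be in [2, 5]")
        if self.geometry not in ("helix", "strand", "ring-pocket"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _build_backbone(phis: list[float], psis: list[float]) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates for a chain with given (phi, psi)."""
    n = len(phis)
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BB["n_ca"], 0.0, 0.0])
    ang = np.radians(_BB["ang_n_ca_c"])
    c0 = ca0 + _BB["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(n - 1):
        r = res[i]
        n_next = place_atom(r["N"], r["CA"], r["C"], _BB["c_n"], _BB["ang_ca_c_n"], psis[i])
        ca_next = place_atom(r["CA"], r["C"], n_next, _BB["n_ca"], _BB["ang_c_n_ca"], _BB["omega"])
        c_next = place_atom(r["C"], n_next, ca_next, _BB["ca_c"], _BB["ang_n_ca_c"], phis[i + 1])
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    for i in range(n):
        psi = psis[i] if i < n - 1 else psis[-1]
        r = res[i]
        r["O"] = place_atom(r["N"], r["CA"], r["C"], _BB["c_o"], _BB["ang_ca_c_o"], psi + 180.0)
    return res


# per-element parameters: rmin_half, epsilon, vdw_radius
_ELEMENT_PARAMS = {
    "C": (1.95, 0.10, 1.9),
    "N": (1.82, 0.17, 1.8),
    "O": (1.77, 0.21, 1.7),
    "S": (2.00, 0.25, 2.0),
}

_BACKBONE_ROWS = [
    ("N", "N", -0.40, "hbond_donor"),
    ("CA", "C", 0.10, "none"),
    ("C", "C", 0.50, "none"),
    ("O", "O", -0.50, "hbond_acceptor"),
]

_SIDECHAIN_ROWS = {
    "ALA": [("CB", "C", -0.10, "hydrophobic")],
    "GLY": [],
    "LEU": [
        ("CB", "C", -0.05, "hydrophobic"),
        ("CG", "C", 0.00, "hydrophobic"),
        ("CD1", "C", -0.05, "hydrophobic"),
        ("CD2", "C", -0.05, "hydrophobic"),
    ],
    "SER": [("CB", "C", 0.05, "none"), ("OG", "O", -0.35, "hbond_donor")],
    "CYS": [("CB", "C", 0.00, "none"), ("SG", "S", -0.15, "none")],
    "VAL": [
        ("CB", "C", -0.05, "hydrophobic"),
        ("CG1", "C", -0.05, "hydrophobic"),
        ("CG2", "C", -0.05, "hydrophobic"),
    ],
    "THR": [
        ("CB", "C", 0.05, "none"),
        ("OG1", "O", -0.35, "hbond_donor"),
        ("CG2", "C", -0.05, "hydrophobic"),
    ],
    "ASP": [
        ("CB", "C", -0.05, "none"),
        ("CG", "C", 0.45, "none"),
        ("OD1", "O", -0.45, "hbond_acceptor"),
        ("OD2", "O", -0.45, "hbond_acceptor"),
    ],
    "PHE": [
        ("CB", "C", -0.05, "hydrophobic"),
        ("CG", "C", 0.00, "hydrophobic"),
        ("CD1", "C", -0.03, "hydrophobic"),
        ("CD2", "C", -0.03, "hydrophobic"),
        ("CE1", "C", -0.03, "hydrophobic"),
        ("CE2", "C", -0.03, "hydrophobic"),
        ("CZ", "C", -0.03, "hydrophobic"),
    ],
}

#: library chi sets per amino acid (degrees), before the clash decoy
_LIB_CHIS = {
    "SER": [((-60.0,), 0.35), ((60.0,), 0.30), ((180.0,), 0.25)],
    "CYS": [((-60.0,), 0.40), ((180.0,), 0.30)],
    "VAL": [((180.0,), 0.45), ((-60.0,), 0.30)],
    "THR": [((-60.0,), 0.45), ((60.0,), 0.30)],
    "LEU": [((-60.0, 180.0), 0.35), ((180.0, 60.0), 0.30)],
    "ASP": [((-60.0, 0.0), 0.35), ((180.0, 0.0), 0.30)],
    "PHE": [((-60.0, 90.0), 0.35), ((180.0, 90.0), 0.30)],
}


def _scaffold_param_rows(aas: set[str], rng: np.random.Generator) -> list[tuple]:
    # backbone charges are shared across amino acids (one jitter per atom
    # name), so a mutation never changes the fixed backbone's parameters
    bb_jitter = {
        name: float(np.round(rng.uniform(-0.02, 0.02), 4)) for name, *_ in _BACKBONE_ROWS
    }
    rows = []
    for aa in sorted(aas):
        for name, el, charge, cls in _BACKBONE_ROWS:
            rmin, eps, vdwr = _ELEMENT_PARAMS[el]
            rows.append((aa, name, charge + bb_jitter[name], rmin, eps, vdwr, cls))
        for name, el, charge, cls in _SIDECHAIN_ROWS[aa]:
            rmin, eps, vdwr = _ELEMENT_PARAMS[el]
            jitter = float(np.round(rng.uniform(-0.02, 0.02), 4))
            rows.append((aa, name, charge + jitter, rmin, eps, vdwr, cls))
    return rows


def _write_tsv(path: Path, rows: list[tuple]) -> None:
    lines = ["res\tatom\tcharge\trmin_half\tepsilon\tvdw_radius\tclass"]
    for res, atom, q, rmin, eps, vdwr, cls in rows:
        lines.append(f"{res}\t{atom}\t{q:.4f}\t{rmin:.4f}\t{eps:.4f}\t{vdwr:.4f}\t{cls}")
    path.write_text("\n".join(lines) + "\n")


def _ligand_coords(n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """A small rigid blob: central atom plus satellites at bond distance."""
    dirs = np.array(
        [
            [1.0, 0.0, 0.0],
            [-0.33, 0.94, 0.0],
            [-0.33, -0.47, 0.82],
            [-0.33, -0.47, -0.82],
        ]
    )
    coords = [np.zeros(3)]
    for k in range(n_atoms - 1):
        bond = 1.45 + float(np.round(rng.uniform(-0.05, 0.05), 3))
        coords.append(dirs[k] * bond)
    return np.array(coords)


def _write_sdf(path: Path, elements: list[str], conformers: list[np.ndarray]) -> None:
    blocks = []
    n = len(elements)
    for ci, coords in enumerate(conformers):
        lines = [f"toy_ligand_{ci}", "  pocketdesign".ljust(20) + "3D", ""]
        lines.append(f"{n:3d}{n - 1:3d}  0  0  0  0  0  0  0  0999 V2000")
        for el, (x, y, z) in zip(elements, coords):
            lines.append(
                f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0"
            )
        for k in range(1, n):  # star topology from the central atom
            lines.append(f"{1:3d}{k + 1:3d}  1  0")
        lines.append("M  END")
        lines.append("$$$$")
        blocks.append("\n".join(lines))
    path.write_text("\n".join(blocks) + "\n")


def _find_clash_chis(scaffold, res_index, aa, params, pocket) -> tuple[float, ...]:
    """Scan chi space for the side chain with maximal scaffold LJ energy.

    The returned chi set is added to the library as a guaranteed-pruned
    decoy rotamer; generation fails loudly if no scanned rotamer reaches
    the pruning threshold.
    """
    scaffold_block = AtomBlock.from_atoms(pocket.fixed_scaffold.atoms)
    labels = _scaffold_label_index(pocket, res_index)
    res = pocket.fixed_scaffold.residues[
        pocket.fixed_scaffold.index_of(scaffold.residues[res_index].chain, scaffold.residues[res_index].seq_id)
    ]
    n_chi = CHI_COUNT[aa]
    grid = np.arange(-180.0, 180.0, 45.0)
    best_chis, best_e = None, -np.inf
    combos = [(c,) for c in grid] if n_chi == 1 else [(c1, c2) for c1 in grid for c2 in grid]
    for chis in combos:
        full = tuple(chis) + (0.0,) * (n_chi - len(chis))
        atoms = _build_sidechain(res, aa, full, params)
        excl = rotamer_scaffold_exclusions(aa, [a.name for a in atoms], labels)
        e = lj_interaction(atoms, scaffold_block, params, excl)
        if e > best_e:
            best_e, best_chis = e, full
    if best_e < 100.0:
        raise RuntimeError(
            f"toy construction failed: no clashing {aa} rotamer found (max LJ {best_e:.1f})"
        )
    return best_chis


def make_toy_system(spec: ToySystemSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a complete toy design project in ``out_dir``.

    Returns a dict of paths: scaffold, scaffold_params, ligand,
    ligand_params, rotamer_lib, config.
    """
    from .pocket import DesignPosition, build_pocket

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pocket_residues

    design_idx = [n // 2 - 1, n // 2]
    design_aas = [spec.aas[i % len(spec.aas)] for i in range(len(design_idx))]
    sequence = []
    for i in range(n):
        if i in design_idx:
            sequence.append(design_aas[design_idx.index(i)])
        else:
            sequence.append("ALA" if i % 2 == 0 else "GLY")

    geometry = "helix" if spec.geometry == "ring-pocket" else spec.geometry
    phi0, psi0 = _GEOMETRIES[geometry]
    phis = [phi0] * n
    psis = [psi0] * n
    if spec.geometry == "ring-pocket":
        # gentle backbone curvature closes the pocket around the ligand
        psis = [psi0 + 8.0 * np.sin(i) for i in range(n)]
    backbone = _build_backbone(phis, psis)

    # parameters (with per-seed charge jitter) must cover natives + mutations
    mutations = {design_idx[0]: ["SER"] if design_aas[0] != "SER" else ["LEU"]}
    all_aas = set(sequence) | {m for ms in mutations.values() for m in ms}
    param_rows = _scaffold_param_rows(all_aas, rng)
    params_path = out / "scaffold_params.tsv"
    _write_tsv(params_path, param_rows)
    params = read_param_table(params_path)

    # assemble the scaffold with native side chains at ideal chi values
    residues = []
    native_chis = {"LEU": (-60.0, 180.0), "SER": (-60.0,), "ALA": (), "GLY": ()}
    for i, aa in enumerate(sequence):
        bb = backbone[i]
        atoms = [
            Atom(name=nm, element=nm[0], coords=bb[nm], vdw_radius=1.0)
            for nm in ("N", "CA", "C", "O")
        ]
        res = Residue(chain="A", seq_id=i + 1, aa=aa, atoms=atoms)
        sc = _build_sidechain(res, aa, native_chis.get(aa, ()), params)
        res.atoms.extend(sc)
        residues.append(res)
    for res in residues:
        for a in res.atoms:
            row = params.scaffold_row(res.aa, a.name)
            a.charge, a.lj_rmin_half, a.lj_epsilon = row["charge"], row["rmin_half"], row["epsilon"]
            a.vdw_radius, a.atom_class = row["vdw_radius"], row["atom_class"]
    scaffold = Scaffold(residues=residues)

    # ligand: placed outward from the design positions' CB midpoint
    # outward along the first design residue's CA->CB vector, which points
    # away from the backbone in every supported geometry
    d0 = scaffold.residues[design_idx[0]]
    outward = d0.atom("CB").coords - d0.atom("CA").coords
    outward /= np.linalg.norm(outward)
    lig_center = d0.atom("CB").coords + outward * (3.2 + float(np.round(rng.uniform(0.0, 0.4), 3)))
    lig_elements = (["C", "O"] + ["C"] * 3)[: spec.ligand_atom_count]
    lig_local = _ligand_coords(spec.ligand_atom_count, rng)
    conformers = []
    for ci in range(spec.n_conformers):
        local = lig_local.copy()
        if ci > 0:  # small internal distortion distinguishes conformers
            local[-1] = local[-1] * (1.0 + 0.05 * ci)
        conformers.append(local - local.mean(axis=0) + lig_center)
    sdf_path = out / "ligand.sdf"
    _write_sdf(sdf_path, lig_elements, conformers)
    lig_rows = []
    lig_classes = {"C": "hydrophobic", "O": "hbond_acceptor"}
    for i, el in enumerate(lig_elements):
        rmin, eps, vdwr = _ELEMENT_PARAMS[el]
        q = -0.3 if el == "O" else 0.05
        lig_rows.append(("LIG", str(i), q, rmin, eps, vdwr, lig_classes[el]))
    lig_params_path = out / "ligand_params.tsv"
    _write_tsv(lig_params_path, lig_rows)

    # rotamer library: backbone-dependent rows at the design positions' bins,
    # plus one scanned clash decoy at the first design position
    positions = [
        DesignPosition(chain="A", seq_id=design_idx[0] + 1,
                       allowed_aas=[design_aas[0]] + mutations[design_idx[0]], is_mutable=True),
        DesignPosition(chain="A", seq_id=design_idx[1] + 1, allowed_aas=[design_aas[1]]),
    ]
    pocket = build_pocket(scaffold, positions)
    bin_width = 10.0
    from .model import RotamerLibrary

    probe = RotamerLibrary(entries={}, bin_width=bin_width)
    lib_rows: list[str] = []
    seen_rows: set[tuple] = set()
    for p, pos in enumerate(positions):
        ri = pocket.position_indices[p]
        phi, psi = backbone_dihedrals(scaffold, ri)
        pb, sb = probe._nearest_bin(phi), probe._nearest_bin(psi)
        for aa in pos.allowed_aas:
            if CHI_COUNT[aa] == 0:
                continue
            for chis, prob in _LIB_CHIS[aa]:
                key = (aa, pb, sb, chis)
                if key in seen_rows:
                    continue
                seen_rows.add(key)
                chi_str = "\t".join(f"{c:.1f}" for c in chis)
                lib_rows.append(f"{aa}\t{pb:.0f}\t{sb:.0f}\t{prob:.2f}\t{chi_str}")
    decoy_aa = design_aas[0]
    decoy_chis = _find_clash_chis(scaffold, design_idx[0], decoy_aa, params, pocket)
    ri = design_idx[0]
    phi, psi = backbone_dihedrals(scaffold, ri)
    pb, sb = probe._nearest_bin(phi), probe._nearest_bin(psi)
    chi_str = "\t".join(f"{c:.1f}" for c in decoy_chis)
    lib_rows.append(f"{decoy_aa}\t{pb:.0f}\t{sb:.0f}\t0.05\t{chi_str}")
    lib_path = out / "rotamers.tsv"
    max_chi = max(CHI_COUNT[aa] for aa in all_aas if CHI_COUNT[aa] > 0)
    chi_cols = "\t".join(f"chi{i + 1}" for i in range(max_chi))
    lib_path.write_text(
        f"# bin_width={bin_width:.0f}\n"
        + f"aa\tphi_bin\tpsi_bin\tprob\t{chi_cols}\n"
        + "\n".join(lib_rows)
        + "\n"
    )

    from .model import write_scaffold

    pdb_path = out / "scaffold.pdb"
    write_scaffold(scaffold, pdb_path)

    config = {
        "scaffold": "scaffold.pdb",
        "scaffold_params": "scaffold_params.tsv",
        "ligand": "ligand.sdf",
        "ligand_params": "ligand_params.tsv",
        "rotamer_lib": "rotamers.tsv",
        "positions": [
            {
                "chain": pos.chain,
                "resid": pos.seq_id,
                "mutations": [a for a in pos.allowed_aas[1:]],
            }
            for pos in positions
        ],
        "flex_radius": 4.0,
        "vdw_prune_threshold": 100.0,
        "include_native_rotamer": False,
        "rot_max": 20.0,
        "rot_step": 20.0,
        "trans_max": 0.5,
        "trans_step": 0.5,
        "binding_scale": 50.0,
        "n_solutions": 3,
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))

    # favourable-contact guarantee: some library rotamer at some design
    # position scores negative against the in-place ligand
    lig_atoms = []
    for i, el in enumerate(lig_elements):
        a = Atom(name=f"{el}{i + 1}", element=el, coords=conformers[0][i], vdw_radius=1.0)
        rmin, eps, vdwr = _ELEMENT_PARAMS[el]
        a.charge = -0.3 if el == "O" else 0.05
        a.lj_rmin_half, a.lj_epsilon, a.vdw_radius = rmin, eps, vdwr
        a.atom_class = lig_classes[el]
        lig_atoms.append(a)
    best = np.inf
    for p, pos in enumerate(positions):
        ri = pocket.position_indices[p]
        res = scaffold.residues[ri]
        for aa in pos.allowed_aas:
            for chis, _prob in _LIB_CHIS.get(aa, []):
                atoms = _build_sidechain(res, aa, chis, params)
                best = min(best, vina_score(lig_atoms, atoms))
    if not best < 0:
        raise RuntimeError(f"toy construction failed: no favourable ligand contact ({best:.4f})")

    return {
        "scaffold": pdb_path,
        "scaffold_params": params_path,
        "ligand": sdf_path,
        "ligand_params": lig_params_path,
        "rotamer_lib": lib_path,
        "config": config_path,
    }


def make_known_optimum_instance(
    seed: int,
    n_positions: int = 3,
    n_rotamers: int = 4,
    n_poses: int = 5,
    margin: float = 1.0,
    binding_scale: float = 50.0,
):
    """Random energy tables with a planted, strictly dominant optimum.

    One assignment is chosen at random and every table entry it touches
    is lowered to (table minimum - margin), making it entry-wise minimal:
    for margin > 0 it is the unique GMEC and every other assignment lies
    at least ``margin`` above it; for margin = 0 it is among the optima.
    Returns ``(tables, planted_solution)``.
    """
    from .energy import EnergyTables
    from .solver import Solution

    rng = np.random.default_rng(seed)
    counts = [n_rotamers] * n_positions
    planted_rot = tuple(int(rng.integers(0, c)) for c in counts)
    planted_pose = int(rng.integers(0, n_poses))

    self_packing = [rng.uniform(0.0, 1.0, c) for c in counts]
    pair_packing = {
        (p, q): rng.uniform(0.0, 1.0, (counts[p], counts[q]))
        for p in range(n_positions)
        for q in range(p + 1, n_positions)
    }
    lig_self = rng.uniform(0.0, 1.0, n_poses)
    lig_pair = [rng.uniform(0.0, 1.0, (n_poses, c)) for c in counts]

    for p, r in enumerate(planted_rot):
        self_packing[p][r] = self_packing[p].min() - margin
    for (p, q), m in pair_packing.items():
        m[planted_rot[p], planted_rot[q]] = m.min() - margin
    lig_self[planted_pose] = lig_self.min() - margin / binding_scale
    for p, m in enumerate(lig_pair):
        m[planted_pose, planted_rot[p]] = m.min() - margin / binding_scale

    tables = EnergyTables(
        self_packing=self_packing,
        pair_packing=pair_packing,
        lig_self_binding=lig_self,
        lig_pair_binding=lig_pair,
        binding_scale=binding_scale,
    )
    planted = Solution.from_assignment(tables, planted_rot, planted_pose)
    return tables, planted
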