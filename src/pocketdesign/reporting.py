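"""Design outputs and evaluation operators.

Covers structure export of solved designs, deterministic text/HTML energy
reports with full per-term breakdowns, the mutant-pair ranking criterion
(a prediction is correct when the variant with experimentally higher
affinity receives the lower computed binding energy), and
backbone-superposed heavy-atom RMSD between designed and reference
structures.
"""

from __future__ import annotations

import hashlib
import html as html_mod
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .energy import EnergyTables, ff_interaction, vina_score, AtomBlock, rotamer_scaffold_exclusions, _scaffold_label_index
from .geometry import superpose, rmsd as coord_rmsd
from .model import Atom, Scaffold, BACKBONE_NAMES, write_pdb
from .solver import Solution

__all__ = [
    "DesignReport",
    "RankVerdict",
    "write_design_structure",
    "rescore_design",
    "rank_pair",
    "pocket_rmsd",
    "ligand_rmsd",
    "build_report",
    "render_report",
    "file_checksum",
]

LIGAND_CHAIN = "L"
LIGAND_RESNAME = "LIG"

#: heavy backbone atoms used for superposition
_BB_HEAVY = ("N", "CA", "C", "O")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# structure export / rescoring
# ---------------------------------------------------------------------------

def design_residue_tuples(pocket, solution: Solution, rotamer_set, pose_set):
    """Residue tuples (chain, seq_id, res_name, atoms, hetero) of a solved design."""
    kept_rots = rotamer_set.kept_rotamers()
    kept_poses = pose_set.kept_poses()
    chosen = {
        pocket.fixed_scaffold.residues[pocket.fixed_scaffold.index_of(p.chain, p.seq_id)].seq_id: None
        for p in pocket.positions
    }
    by_key = {
        (pos.chain, pos.seq_id): kept_rots[i][solution.rotamer_choice[i]]
        for i, pos in enumerate(pocket.positions)
    }
    out = []
    for res in pocket.fixed_scaffold.residues:
        key = (res.chain, res.seq_id)
        if key in by_key:
            rot = by_key[key]
            atoms = list(res.atoms) + list(rot.atoms)
            out.append((res.chain, res.seq_id, rot.aa, atoms, False))
        else:
            out.append((res.chain, res.seq_id, res.aa, list(res.atoms), False))
    pose = kept_poses[solution.pose_choice]
    out.append((LIGAND_CHAIN, 1, LIGAND_RESNAME, list(pose.atoms), True))
    return out


def write_design_structure(pocket, solution: Solution, rotamer_set, pose_set, out_path) -> None:
    """Write fixed scaffold + chosen rotamers + chosen pose as a PDB file.

    The ligand goes out as HETATM records on its own chain.
    """
    write_pdb(out_path, design_residue_tuples(pocket, solution, rotamer_set, pose_set))


def rescore_design(
    pdb_path: str | Path,
    scaffold_params_path: str | Path,
    ligand_params_path: str | Path,
    design_positions: list[tuple[str, int]],
    params=None,
    weights=None,
    binding_scale: float = 50.0,
) -> tuple[float, float, float]:
    """Re-read a written design structure and recompute its energies.

    Returns (total, packing, raw binding).  Packing sums the interaction
    of each design-position side chain with the fixed part and with the
    other design side chains (bonded exclusions applied); binding is the
    empirical score of the ligand against all protein atoms.  Limited by
    the 1e-3 Å coordinate precision of the PDB format.
    """
    from .model import read_scaffold, read_param_table, ForceFieldParams
    from .pocket import DesignPosition, build_pocket
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(pdb_path))
    arr = pdb.get_structure(model=1)
    is_lig = arr.chain_id == LIGAND_CHAIN

    # protein part -> temp scaffold read via the standard reader
    import io, tempfile, os

    prot = arr[~is_lig]
    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        tmp = fh.name
    pdb_out = PDBFile()
    pdb_out.set_structure(prot)
    pdb_out.write(tmp)
    try:
        scaffold = read_scaffold(tmp, scaffold_params_path)
    finally:
        os.unlink(tmp)

    lig_params = read_param_table(ligand_params_path, ligand=True)
    lig_atoms = []
    lig = arr[is_lig]
    for i in range(lig.array_length()):
        a = Atom(name=lig.atom_name[i], element=lig.element[i], coords=lig.coord[i], vdw_radius=1.0)
        row = lig_params.ligand[i]
        a.charge, a.lj_rmin_half, a.lj_epsilon = row["charge"], row["rmin_half"], row["epsilon"]
        a.vdw_radius, a.atom_class = row["vdw_radius"], row["atom_class"]
        lig_atoms.append(a)

    positions = [DesignPosition(chain=c, seq_id=s, allowed_aas=["ALA"]) for c, s in design_positions]
    for p, (c, s) in zip(positions, design_positions):
        p.allowed_aas = [scaffold.residues[scaffold.index_of(c, s)].aa]
    pocket = build_pocket(scaffold, positions)
    ff_params = params or ForceFieldParams()
    groups = pocket.native_sidechains
    packing = 0.0
    fixed_block = AtomBlock.from_atoms(pocket.fixed_scaffold.atoms)
    for p, group in enumerate(groups):
        if not group:
            continue
        labels = _scaffold_label_index(pocket, pocket.position_indices[p])
        aa = scaffold.residues[pocket.position_indices[p]].aa
        excl = rotamer_scaffold_exclusions(aa, [a.name for a in group], labels)
        packing += ff_interaction(group, fixed_block, ff_params, excl)
    for p in range(len(groups)):
        for q in range(p + 1, len(groups)):
            if groups[p] and groups[q]:
                packing += ff_interaction(groups[p], groups[q], ff_params)
    binding = vina_score(lig_atoms, AtomBlock.from_atoms(scaffold.atoms), weights)
    total = packing + binding_scale * binding
    return total, packing, binding


# ---------------------------------------------------------------------------
# ranking criterion
# ---------------------------------------------------------------------------

@dataclass
class RankVerdict:
    by_binding: str  # "correct" | "incorrect"
    by_total: str


def _rank_one(low_value: float, high_value: float) -> str:
    """Correct iff the experimentally stronger binder scores strictly lower."""
    if high_value == low_value:
        warnings.warn("exact energy tie; ranked as incorrect (conservative)")
        return "incorrect"
    return "correct" if high_value < low_value else "incorrect"


def rank_pair(design_low_affinity: Solution, design_high_affinity: Solution) -> RankVerdict:
    """Prediction correctness for a mutant pair with known affinity order.

    The first argument is the design of the experimentally *weaker*
    binder, the second of the *stronger* one.  The prediction is correct
    when the stronger binder's computed binding energy is lower; the same
    rule applied to total energies gives the independent by-total verdict.
    Exact ties are conservatively incorrect.
    """
    return RankVerdict(
        by_binding=_rank_one(
            design_low_affinity.binding_energy_raw, design_high_affinity.binding_energy_raw
        ),
        by_total=_rank_one(design_low_affinity.total_energy, design_high_affinity.total_energy),
    )


# ---------------------------------------------------------------------------
# RMSD operators
# ---------------------------------------------------------------------------

def _matched_backbone(ref: Scaffold, other: Scaffold) -> tuple[np.ndarray, np.ndarray]:
    ref_c, oth_c = [], []
    for r_res in ref.residues:
        o_res = other.residues[other.index_of(r_res.chain, r_res.seq_id)]
        for name in _BB_HEAVY:
            if r_res.has_atom(name) and o_res.has_atom(name):
                ref_c.append(r_res.atom(name).coords)
                oth_c.append(o_res.atom(name).coords)
    return np.array(ref_c), np.array(oth_c)


def _sidechain_heavy_map(res) -> dict[str, np.ndarray]:
    return {
        a.name: a.coords
        for a in res.atoms
        if a.name not in BACKBONE_NAMES and not a.is_hydrogen
    }


def pocket_rmsd(
    reference: Scaffold,
    designed: Scaffold,
    flexible_positions: list[tuple[str, int]],
) -> float:
    """Side-chain heavy-atom RMSD over flexible residues.

    The designed structure is first rigidly superposed onto the reference
    using all backbone heavy atoms (Kabsch); the RMSD is then computed
    over the side-chain heavy atoms of the listed flexible residues only.
    Mismatched side-chain atom names are a hard error.
    """
    ref_bb, des_bb = _matched_backbone(reference, designed)
    ref_sc, des_sc = [], []
    offenders = []
    for chain, seq_id in flexible_positions:
        r_res = reference.residues[reference.index_of(chain, seq_id)]
        d_res = designed.residues[designed.index_of(chain, seq_id)]
        r_map, d_map = _sidechain_heavy_map(r_res), _sidechain_heavy_map(d_res)
        if set(r_map) != set(d_map):
            offenders.append(
                f"{chain}{seq_id}: {sorted(set(r_map) ^ set(d_map))}"
            )
            continue
        for name in sorted(r_map):
            ref_sc.append(r_map[name])
            des_sc.append(d_map[name])
    if offenders:
        raise ValueError("side-chain atom mismatch at " + "; ".join(offenders))
    if not ref_sc:
        return 0.0
    des_sc_fit = superpose(des_bb, ref_bb, np.array(des_sc))
    return coord_rmsd(np.array(ref_sc), des_sc_fit)


def ligand_rmsd(
    reference: Scaffold,
    designed: Scaffold,
    reference_ligand: list[Atom],
    designed_ligand: list[Atom],
) -> float:
    """Ligand heavy-atom RMSD after backbone superposition of the proteins."""
    ref_bb, des_bb = _matched_backbone(reference, designed)
    ref_l = np.array([a.coords for a in reference_ligand if not a.is_hydrogen])
    des_l = np.array([a.coords for a in designed_ligand if not a.is_hydrogen])
    if ref_l.shape != des_l.shape:
        raise ValueError("ligand heavy-atom counts differ")
    des_l_fit = superpose(des_bb, ref_bb, des_l)
    return coord_rmsd(ref_l, des_l_fit)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class DesignReport:
    """Ranked solutions with per-term energy breakdowns and provenance."""

    solutions: list[Solution]
    breakdowns: list[dict]
    position_labels: list[str]
    provenance: dict = field(default_factory=dict)


def build_report(
    tables: EnergyTables,
    solutions: list[Solution],
    position_labels: list[str] | None = None,
    rotamer_set=None,
    provenance: dict | None = None,
) -> DesignReport:
    """Assemble per-solution breakdowns from the energy tables.

    Every breakdown satisfies: sum of packing terms = packing energy, sum
    of binding terms = raw binding, and total = packing +
    binding_scale * binding.
    """
    n_pos = tables.n_positions
    labels = position_labels or [f"pos{p}" for p in range(n_pos)]
    kept = rotamer_set.kept_rotamers() if rotamer_set is not None else None

    breakdowns = []
    for sol in solutions:
        terms: dict = {"self": {}, "pair": {}, "ligand": {}}
        for p, r in enumerate(sol.rotamer_choice):
            name = labels[p]
            if kept is not None:
                rot = kept[p][r]
                name = f"{labels[p]}:{rot.aa}[{r}]"
            terms["self"][name] = float(tables.self_packing[p][r])
        for (p, q), m in sorted(tables.pair_packing.items()):
            terms["pair"][f"{labels[p]}-{labels[q]}"] = float(
                m[sol.rotamer_choice[p], sol.rotamer_choice[q]]
            )
        terms["ligand"]["pose-scaffold"] = float(tables.lig_self_binding[sol.pose_choice])
        for p in range(n_pos):
            terms["ligand"][f"pose-{labels[p]}"] = float(
                tables.lig_pair_binding[p][sol.pose_choice, sol.rotamer_choice[p]]
            )
        breakdowns.append(terms)
    return DesignReport(
        solutions=list(solutions),
        breakdowns=breakdowns,
        position_labels=list(labels),
        provenance=provenance or {},
    )


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def _report_rows(report: DesignReport) -> list[tuple[str, str]]:
    rows = []
    for rank, (sol, terms) in enumerate(zip(report.solutions, report.breakdowns), start=1):
        rows.append((f"solution {rank}", ""))
        rows.append(("  assignment", " ".join(map(str, sol.index_vector))))
        for name, v in terms["self"].items():
            rows.append((f"  self {name}", _fmt(v)))
        for name, v in terms["pair"].items():
            rows.append((f"  pair {name}", _fmt(v)))
        for name, v in terms["ligand"].items():
            rows.append((f"  binding {name}", _fmt(v)))
        rows.append(("  packing energy", _fmt(sol.packing_energy)))
        rows.append(("  binding energy (raw)", _fmt(sol.binding_energy_raw)))
        rows.append(("  binding energy (scaled)", _fmt(sol.binding_energy_scaled)))
        rows.append(("  total energy", _fmt(sol.total_energy)))
    return rows


def render_report(report: DesignReport, fmt: str = "text", out_path: str | Path | None = None) -> str:
    """Deterministic text or HTML rendering (stable order, 4 decimals)."""
    if fmt not in ("text", "html"):
        raise ValueError(f"unknown report format {fmt!r}")
    rows = _report_rows(report)
    prov = json.dumps(report.provenance, sort_keys=True)
    if fmt == "text":
        width = max((len(k) for k, _ in rows), default=0) + 2
        lines = ["pocket design report", "=" * 20, f"provenance: {prov}", ""]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        out = "\n".join(lines) + "\n"
    else:
        esc = html_mod.escape
        body = "\n".join(
            f"<tr><td>{esc(k)}</td><td>{esc(v)}</td></tr>" for k, v in rows
        )
        out = (
            "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\"/>"
            "<title>pocket design report</title></head><body>"
            f"<h1>pocket design report</h1><p>provenance: {esc(prov)}</p>"
            f"<table>\n{body}\n</table></body></html>\n"
        )
    if out_path is not None:
        Path(out_path).write_text(out)
    return out
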