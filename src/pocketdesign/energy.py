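"""Self/pairwise interaction energies on two tracks.

The design problem is made solvable by decomposing the pocket energy into
terms that depend on at most one or two variable groups (rotamers, ligand
poses):

* *packing track* — molecular-mechanics non-bonded energy (12-6
  Lennard-Jones + Coulomb) between protein groups, using the per-atom
  parameters attached at read time;
* *binding track* — an empirical AutoDock-Vina-style interaction score
  between ligand poses and protein atoms, evaluated on heavy atoms with
  an 8 Å distance cutoff.

Because every term is strictly pairwise over atoms and the packing track
applies no cross-group distance cutoff, the decomposition is exact: for
any full assignment the sum of table entries reproduces the directly
evaluated inter-group energy of the assembled system to machine
precision.  Binding entries enter the solver objective multiplied by
``binding_scale`` (default 50) so that the empirical score competes with
the force-field packing energies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .model import Atom, ForceFieldParams

__all__ = [
    "AtomBlock",
    "ScoringWeights",
    "EnergyTables",
    "lj_energy",
    "coulomb_energy",
    "ff_interaction",
    "lj_interaction",
    "vina_score",
    "compute_tables",
    "save_tables",
    "load_tables",
]

EXCLUDED = "excluded"
SCALE14 = "scale14"


@dataclass
class AtomBlock:
    """Structure-of-arrays view of an atom group (hot-path container)."""

    coords: np.ndarray
    charge: np.ndarray
    rmin_half: np.ndarray
    epsilon: np.ndarray
    vdw_radius: np.ndarray
    hydrophobic: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    heavy: np.ndarray

    @classmethod
    def from_atoms(cls, atoms: list[Atom]) -> "AtomBlock":
        n = len(atoms)
        return cls(
            coords=np.array([a.coords for a in atoms], float).reshape(n, 3),
            charge=np.array([a.charge for a in atoms], float),
            rmin_half=np.array([a.lj_rmin_half for a in atoms], float),
            epsilon=np.array([a.lj_epsilon for a in atoms], float),
            vdw_radius=np.array([a.vdw_radius for a in atoms], float),
            hydrophobic=np.array([a.atom_class == "hydrophobic" for a in atoms]),
            donor=np.array([a.atom_class == "hbond_donor" for a in atoms]),
            acceptor=np.array([a.atom_class == "hbond_acceptor" for a in atoms]),
            heavy=np.array([not a.is_hydrogen for a in atoms]),
        )

    @property
    def n(self) -> int:
        return len(self.charge)


def _as_block(group) -> AtomBlock:
    return group if isinstance(group, AtomBlock) else AtomBlock.from_atoms(group)


@dataclass
class ScoringWeights:
    """Vina-style empirical scoring weights (published Vina defaults)."""

    w_gauss1: float = -0.035579
    w_gauss2: float = -0.005156
    w_repulsion: float = 0.840245
    w_hydrophobic: float = -0.035069
    w_hbond: float = -0.587439
    cutoff: float = 8.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


# ---------------------------------------------------------------------------
# pair-level terms
# ---------------------------------------------------------------------------

def lj_energy(atom_i: Atom, atom_j: Atom, r: float) -> float:
    """12-6 Lennard-Jones energy (kcal/mol) at separation ``r`` (Å).

    Lorentz-Berthelot style combination: r_min = rmin_half_i + rmin_half_j,
    epsilon = sqrt(eps_i * eps_j).  The minimum is -epsilon at r = r_min and
    the root sits at r = r_min * 2^(-1/6).
    """
    if r <= 0:
        raise ValueError("lj_energy: r must be > 0")
    r_min = atom_i.lj_rmin_half + atom_j.lj_rmin_half
    eps = np.sqrt(atom_i.lj_epsilon * atom_j.lj_epsilon)
    q = (r_min / r) ** 6
    return float(eps * (q * q - 2.0 * q))


def coulomb_energy(
    atom_i: Atom, atom_j: Atom, r: float, coulomb_constant: float = 332.0636
) -> float:
    """Coulomb energy (kcal/mol): k q_i q_j / r, charges in e, r in Å."""
    if r <= 0:
        raise ValueError("coulomb_energy: r must be > 0")
    return float(coulomb_constant * atom_i.charge * atom_j.charge / r)


def _scale_matrices(
    n_a: int, n_b: int, exclusions, lj_14: float, coul_14: float
) -> tuple[np.ndarray | None, np.ndarray | None]:
    if not exclusions:
        return None, None
    lj_s = np.ones((n_a, n_b))
    c_s = np.ones((n_a, n_b))
    for (i, j), kind in exclusions.items():
        if kind == EXCLUDED:
            lj_s[i, j] = 0.0
            c_s[i, j] = 0.0
        elif kind == SCALE14:
            lj_s[i, j] = lj_14
            c_s[i, j] = coul_14
        else:
            raise ValueError(f"unknown exclusion kind {kind!r}")
    return lj_s, c_s


def _check_distances(d: np.ndarray) -> None:
    if np.any(d <= 0):
        raise ValueError("coincident atoms: zero interatomic distance")


def ff_interaction(
    group_a,
    group_b,
    params: ForceFieldParams | None = None,
    exclusions: dict[tuple[int, int], str] | None = None,
) -> float:
    """Force-field interaction energy between two disjoint atom groups.

    Sums Lennard-Jones + Coulomb over all cross pairs (strictly
    inter-group; no intra-group terms).  ``exclusions`` maps
    ``(index_in_a, index_in_b)`` to ``"excluded"`` (1-2/1-3 pairs, zeroed)
    or ``"scale14"`` (three-bond pairs, scaled by the force field's 1-4
    factors) — only relevant across the CA/CB cut of a rotamer's own
    residue.
    """
    params = params or ForceFieldParams()
    a, b = _as_block(group_a), _as_block(group_b)
    if a.n == 0 or b.n == 0:
        return 0.0
    d = cdist(a.coords, b.coords)
    _check_distances(d)
    r_min = a.rmin_half[:, None] + b.rmin_half[None, :]
    eps = np.sqrt(a.epsilon[:, None] * b.epsilon[None, :])
    q6 = (r_min / d) ** 6
    e_lj = eps * (q6 * q6 - 2.0 * q6)
    e_c = params.coulomb_constant * a.charge[:, None] * b.charge[None, :] / d
    lj_s, c_s = _scale_matrices(a.n, b.n, exclusions, params.lj_14_scale, params.coulomb_14_scale)
    if lj_s is not None:
        e_lj = e_lj * lj_s
        e_c = e_c * c_s
    return float(e_lj.sum() + e_c.sum())


def lj_interaction(
    group_a,
    group_b,
    params: ForceFieldParams | None = None,
    exclusions: dict[tuple[int, int], str] | None = None,
) -> float:
    """Lennard-Jones-only inter-group energy (the pruning 'vdW energy')."""
    params = params or ForceFieldParams()
    a, b = _as_block(group_a), _as_block(group_b)
    if a.n == 0 or b.n == 0:
        return 0.0
    d = cdist(a.coords, b.coords)
    _check_distances(d)
    r_min = a.rmin_half[:, None] + b.rmin_half[None, :]
    eps = np.sqrt(a.epsilon[:, None] * b.epsilon[None, :])
    q6 = (r_min / d) ** 6
    e_lj = eps * (q6 * q6 - 2.0 * q6)
    lj_s, _ = _scale_matrices(a.n, b.n, exclusions, params.lj_14_scale, params.coulomb_14_scale)
    if lj_s is not None:
        e_lj = e_lj * lj_s
    return float(e_lj.sum())


def _ramp(d: np.ndarray, a: float, b: float) -> np.ndarray:
    """1 for d <= a, 0 for d >= b, linear in between (a < b)."""
    return np.clip((b - d) / (b - a), 0.0, 1.0)


def vina_score(ligand_atoms, receptor_atoms, weights: ScoringWeights | None = None) -> float:
    """Empirical Vina-style protein-ligand interaction score.

    Heavy atoms only.  For each pair within the distance cutoff the score
    uses the surface distance d = r - (R_i + R_j) (van der Waals radii):

    * gauss1:      exp(-(d/0.5)^2)
    * gauss2:      exp(-((d-3)/2)^2)
    * repulsion:   d^2 for d < 0
    * hydrophobic: ramp(d; 0.5, 1.5) if both atoms are hydrophobic
    * hbond:       ramp(d; -0.7, 0) for donor-acceptor pairs

    This is an interaction rescore: no rotatable-bond/entropy
    normalisation is applied.
    """
    weights = weights or ScoringWeights()
    lig, rec = _as_block(ligand_atoms), _as_block(receptor_atoms)
    li, ri = np.where(lig.heavy)[0], np.where(rec.heavy)[0]
    if li.size == 0 or ri.size == 0:
        return 0.0
    r = cdist(lig.coords[li], rec.coords[ri])
    within = r <= weights.cutoff
    if not np.any(within):
        return 0.0
    d = r - (lig.vdw_radius[li][:, None] + rec.vdw_radius[ri][None, :])
    gauss1 = np.exp(-((d / 0.5) ** 2))
    gauss2 = np.exp(-(((d - 3.0) / 2.0) ** 2))
    repulsion = np.where(d < 0, d * d, 0.0)
    both_phob = lig.hydrophobic[li][:, None] & rec.hydrophobic[ri][None, :]
    hydrophobic = _ramp(d, 0.5, 1.5) * both_phob
    da = (
        lig.donor[li][:, None] & rec.acceptor[ri][None, :]
    ) | (lig.acceptor[li][:, None] & rec.donor[ri][None, :])
    hbond = _ramp(d, -0.7, 0.0) * da
    per_pair = (
        weights.w_gauss1 * gauss1
        + weights.w_gauss2 * gauss2
        + weights.w_repulsion * repulsion
        + weights.w_hydrophobic * hydrophobic
        + weights.w_hbond * hbond
    )
    return float(per_pair[within].sum())


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------

@dataclass
class EnergyTables:
    """Decomposed pocket energies.

    ``self_packing[p][r]`` — rotamer r at position p vs the fixed scaffold
    (kcal/mol); ``pair_packing[(p, q)][r, s]`` (p < q) — rotamer-rotamer;
    ``lig_self_binding[l]`` — pose l vs the fixed scaffold (score units);
    ``lig_pair_binding[p][l, r]`` — pose l vs rotamer r at position p.
    Binding entries are stored raw; the solver objective multiplies them
    by ``binding_scale``.
    """

    self_packing: list[np.ndarray]
    pair_packing: dict[tuple[int, int], np.ndarray]
    lig_self_binding: np.ndarray
    lig_pair_binding: list[np.ndarray]
    binding_scale: float = 50.0

    def __post_init__(self) -> None:
        self.validate()

    # -- shape / sanity -----------------------------------------------------
    @property
    def n_positions(self) -> int:
        return len(self.self_packing)

    @property
    def n_rotamers(self) -> list[int]:
        return [len(v) for v in self.self_packing]

    @property
    def n_poses(self) -> int:
        return len(self.lig_self_binding)

    def validate(self) -> None:
        n_rot = self.n_rotamers
        for p, n in enumerate(n_rot):
            if n == 0:
                raise ValueError(f"position {p} has no rotamers")
        if self.n_poses == 0:
            raise ValueError("no ligand poses")
        for (p, q), m in self.pair_packing.items():
            if not (0 <= p < q < self.n_positions):
                raise ValueError(f"bad pair key ({p}, {q})")
            if m.shape != (n_rot[p], n_rot[q]):
                raise ValueError(
                    f"pair ({p},{q}) shape {m.shape} != ({n_rot[p]}, {n_rot[q]})"
                )
        if len(self.lig_pair_binding) != self.n_positions:
            raise ValueError("one ligand-pair matrix required per position")
        for p, m in enumerate(self.lig_pair_binding):
            if m.shape != (self.n_poses, n_rot[p]):
                raise ValueError(
                    f"ligand pair {p} shape {m.shape} != ({self.n_poses}, {n_rot[p]})"
                )
        for arr in self._all_arrays():
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite energy table entry")

    def _all_arrays(self):
        yield from self.self_packing
        yield from self.pair_packing.values()
        yield self.lig_self_binding
        yield from self.lig_pair_binding

    # -- evaluation ---------------------------------------------------------
    def assignment_energy(
        self, rotamer_choice: tuple[int, ...], pose_choice: int
    ) -> tuple[float, float, float]:
        """(total, packing, raw binding) for a full assignment.

        total = packing + binding_scale * binding_raw.
        """
        if len(rotamer_choice) != self.n_positions:
            raise ValueError("one rotamer index per position required")
        packing = sum(self.self_packing[p][r] for p, r in enumerate(rotamer_choice))
        for (p, q), m in self.pair_packing.items():
            packing += m[rotamer_choice[p], rotamer_choice[q]]
        binding = self.lig_self_binding[pose_choice]
        for p, r in enumerate(rotamer_choice):
            binding += self.lig_pair_binding[p][pose_choice, r]
        total = packing + self.binding_scale * binding
        return float(total), float(packing), float(binding)


def rotamer_scaffold_exclusions(
    aa: str, atom_names: list[str], scaffold_index: dict[str, int]
) -> dict[tuple[int, int], str]:
    """Bonded-exclusion map between a rotamer group and the fixed scaffold.

    A rotamer group attaches to the scaffold through the single CA-CB
    bond, so the graph distance from a side-chain atom to any backbone
    atom is its in-group distance to CB plus the CB-to-backbone distance.
    Pairs within two bonds are excluded; three-bond pairs are 1-4 scaled.
    ``scaffold_index`` maps labels ``CA,N,C,O,H,HA,prev:C,next:N`` of the
    rotamer's own residue (and bonded neighbours) to flat atom indices of
    the fixed scaffold; absent labels are skipped.
    """
    from .templates import sidechain_bonds

    # in-group bond distance to CB
    adj: dict[str, set[str]] = {}
    for x, y in sidechain_bonds(aa):
        if x == "CA":
            continue  # the CA-CB attachment is handled via the closed form
        adj.setdefault(x, set()).add(y)
        adj.setdefault(y, set()).add(x)
    dist = {"CB": 0}
    frontier = ["CB"]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt

    # bond distance from CB to scaffold atoms (through CA)
    backbone_dist = {"CA": 1, "N": 2, "C": 2, "HA": 2, "O": 3, "H": 3, "prev:C": 3, "next:N": 3}
    out: dict[tuple[int, int], str] = {}
    for i, name in enumerate(atom_names):
        d_cb = dist.get(name)
        if d_cb is None or d_cb > 2:
            continue
        for label, d_bb in backbone_dist.items():
            j = scaffold_index.get(label)
            if j is None:
                continue
            d_tot = d_cb + d_bb
            if d_tot <= 2:
                out[(i, j)] = EXCLUDED
            elif d_tot == 3:
                out[(i, j)] = SCALE14
    return out


def _scaffold_label_index(pocket, pos_index: int) -> dict[str, int]:
    """Flat fixed-scaffold indices for a design position's bonded backbone."""
    scaffold = pocket.fixed_scaffold
    offsets = []
    total = 0
    for r in scaffold.residues:
        offsets.append(total)
        total += len(r.atoms)
    ri = scaffold.index_of(
        pocket.scaffold.residues[pos_index].chain, pocket.scaffold.residues[pos_index].seq_id
    )
    labels: dict[str, int] = {}
    res = scaffold.residues[ri]
    for k, a in enumerate(res.atoms):
        if a.name in ("CA", "N", "C", "O", "H", "HA"):
            labels[a.name] = offsets[ri] + k
    prev, nxt = scaffold.neighbors(ri)
    if prev is not None:
        for k, a in enumerate(scaffold.residues[prev].atoms):
            if a.name == "C":
                labels["prev:C"] = offsets[prev] + k
    if nxt is not None:
        for k, a in enumerate(scaffold.residues[nxt].atoms):
            if a.name == "N":
                labels["next:N"] = offsets[nxt] + k
    return labels


def _table_blocks(n_positions: int) -> list[tuple]:
    """Deterministic work-block list: self, pair, ligand-self, ligand-pair."""
    blocks: list[tuple] = [("self", p) for p in range(n_positions)]
    blocks += [("pair", p, q) for p in range(n_positions) for q in range(p + 1, n_positions)]
    blocks.append(("lig_self",))
    blocks += [("lig_pair", p) for p in range(n_positions)]
    return blocks


def compute_tables(
    pocket,
    rotamer_set,
    pose_set,
    params: ForceFieldParams | None = None,
    weights: ScoringWeights | None = None,
    binding_scale: float = 50.0,
    workers: int = 1,
    progress: bool = False,
) -> EnergyTables:
    """Compute all self/pairwise tables for pruned rotamers and poses.

    Work is split into independent blocks (one per self vector, pair
    matrix, or ligand table); blocks may be evaluated by multiple worker
    processes, and results are assembled in block order so the tables are
    bit-identical regardless of ``workers``.
    """
    params = params or ForceFieldParams()
    weights = weights or ScoringWeights()
    rot_groups = rotamer_set.kept_rotamers()
    poses = pose_set.kept_poses()
    if not poses:
        raise ValueError("no ligand poses available for table computation")
    for p, rots in enumerate(rot_groups):
        if not rots:
            raise ValueError(f"position {p} has no rotamers after pruning")

    scaffold_block = AtomBlock.from_atoms(pocket.fixed_scaffold.atoms)
    rot_blocks = [[AtomBlock.from_atoms(r.atoms) for r in rots] for rots in rot_groups]
    pose_blocks = [AtomBlock.from_atoms(p.atoms) for p in poses]
    n_pos = len(rot_groups)

    excl_cache: dict[tuple[int, str], dict] = {}

    def exclusions_for(p: int, rot) -> dict:
        key = (p, rot.aa)
        if key not in excl_cache:
            labels = _scaffold_label_index(pocket, pocket.position_indices[p])
            names = [a.name for a in rot.atoms]
            excl_cache[key] = rotamer_scaffold_exclusions(rot.aa, names, labels)
        return excl_cache[key]

    def run_block(block: tuple):
        kind = block[0]
        if kind == "self":
            p = block[1]
            return np.array(
                [
                    ff_interaction(rb, scaffold_block, params, exclusions_for(p, rot))
                    for rot, rb in zip(rot_groups[p], rot_blocks[p])
                ]
            )
        if kind == "pair":
            p, q = block[1], block[2]
            m = np.empty((len(rot_blocks[p]), len(rot_blocks[q])))
            for i, rb in enumerate(rot_blocks[p]):
                for j, sb in enumerate(rot_blocks[q]):
                    m[i, j] = ff_interaction(rb, sb, params)
            return m
        if kind == "lig_self":
            return np.array([vina_score(pb, scaffold_block, weights) for pb in pose_blocks])
        if kind == "lig_pair":
            p = block[1]
            m = np.empty((len(pose_blocks), len(rot_blocks[p])))
            for li, pb in enumerate(pose_blocks):
                for j, rb in enumerate(rot_blocks[p]):
                    m[li, j] = vina_score(pb, rb, weights)
            return m
        raise ValueError(f"unknown block {block}")

    blocks = _table_blocks(n_pos)
    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(delayed(run_block)(b) for b in blocks)
    else:
        iterator = blocks
        if progress:
            from tqdm import tqdm

            iterator = tqdm(blocks, desc="energy blocks", unit="block")
        results = [run_block(b) for b in iterator]

    by_block = dict(zip(blocks, results))
    return EnergyTables(
        self_packing=[by_block[("self", p)] for p in range(n_pos)],
        pair_packing={
            (p, q): by_block[("pair", p, q)]
            for p in range(n_pos)
            for q in range(p + 1, n_pos)
        },
        lig_self_binding=by_block[("lig_self",)],
        lig_pair_binding=[by_block[("lig_pair", p)] for p in range(n_pos)],
        binding_scale=binding_scale,
    )


# ---------------------------------------------------------------------------
# on-disk layout: one text file per table plus a manifest
# ---------------------------------------------------------------------------

_FMT = "%.17g"


def save_tables(tables: EnergyTables, out_dir: str | Path, config_hash: str = "") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_positions": tables.n_positions,
        "n_rotamers": tables.n_rotamers,
        "n_poses": tables.n_poses,
        "binding_scale": tables.binding_scale,
        "config_hash": config_hash,
    }
    (out / "tables.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    for p, v in enumerate(tables.self_packing):
        np.savetxt(out / f"self_{p}.csv", v, fmt=_FMT, delimiter=",")
    for (p, q), m in tables.pair_packing.items():
        np.savetxt(out / f"pair_{p}_{q}.csv", np.atleast_2d(m), fmt=_FMT, delimiter=",")
    np.savetxt(out / "lig_self.csv", tables.lig_self_binding, fmt=_FMT, delimiter=",")
    for p, m in enumerate(tables.lig_pair_binding):
        np.savetxt(out / f"lig_pair_{p}.csv", np.atleast_2d(m), fmt=_FMT, delimiter=",")


def load_tables(in_dir: str | Path) -> EnergyTables:
    src = Path(in_dir)
    manifest = json.loads((src / "tables.json").read_text())
    n_pos = manifest["n_positions"]
    n_rot = manifest["n_rotamers"]
    n_pose = manifest["n_poses"]
    self_packing = [
        np.loadtxt(src / f"self_{p}.csv", delimiter=",").reshape(n_rot[p])
        for p in range(n_pos)
    ]
    pair_packing = {
        (p, q): np.loadtxt(src / f"pair_{p}_{q}.csv", delimiter=",").reshape(n_rot[p], n_rot[q])
        for p in range(n_pos)
        for q in range(p + 1, n_pos)
    }
    lig_self = np.loadtxt(src / "lig_self.csv", delimiter=",").reshape(n_pose)
    lig_pair = [
        np.loadtxt(src / f"lig_pair_{p}.csv", delimiter=",").reshape(n_pose, n_rot[p])
        for p in range(n_pos)
    ]
    return EnergyTables(
        self_packing=self_packing,
        pair_packing=pair_packing,
        lig_self_binding=lig_self,
        lig_pair_binding=lig_pair,
        binding_scale=manifest["binding_scale"],
    )
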