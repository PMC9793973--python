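"""Flexible-position selection and pocket partitioning.

A residue becomes flexible when any of its side-chain heavy atoms lies
within a cutoff (default 4 Å) of a ligand heavy atom or of the Cα of a
mutation position.  Residues at segment termini or involved in disulfide
bridges are then removed from the flexible set (static rules), and the
system is split into a fixed scaffold (full backbone + side chains of
non-design residues) and per-position variable groups (side-chain atoms
beyond Cα of the design positions, which the rotamer sampler rebuilds).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .model import Atom, LigandConformer, Residue, Scaffold, BACKBONE_NAMES

__all__ = [
    "DesignPosition",
    "PocketModel",
    "select_flexible",
    "apply_static_rules",
    "build_pocket",
]

DISULFIDE_SG_MAX = 2.3  # Å, CYS SG-SG distance defining a disulfide bridge


@dataclass
class DesignPosition:
    chain: str
    seq_id: int
    allowed_aas: list[str]
    is_mutable: bool = False

    def __post_init__(self) -> None:
        if not self.allowed_aas:
            raise ValueError(f"position {self.chain}{self.seq_id}: allowed_aas is empty")


@dataclass
class PocketModel:
    """The partitioned design system.

    ``fixed_scaffold`` shares no atom with any variable group: design
    positions keep only their backbone (N, CA, C, O and backbone
    hydrogens); their stripped native side chains are retained in
    ``native_sidechains`` for bookkeeping and the partition property.
    """

    scaffold: Scaffold
    positions: list[DesignPosition]
    fixed_scaffold: Scaffold
    position_indices: list[int]
    native_sidechains: list[list[Atom]] = field(default_factory=list)

    @property
    def n_positions(self) -> int:
        return len(self.positions)


def _sidechain_heavy_coords(res: Residue) -> np.ndarray:
    coords = [a.coords for a in res.sidechain_atoms if not a.is_hydrogen]
    return np.array(coords).reshape(-1, 3)


def select_flexible(
    scaffold: Scaffold,
    ligand: LigandConformer,
    mutation_positions: list[dict],
    radius: float = 4.0,
    apply_static: bool = True,
) -> list[DesignPosition]:
    """Select design positions around the ligand and the mutation sites.

    ``mutation_positions`` entries are dicts with keys ``chain``,
    ``resid`` and optional ``mutations`` (list of 3-letter codes; the
    native amino acid is always allowed).  Flexibility criterion: minimum
    distance from any side-chain heavy atom of the candidate residue to
    any ligand heavy atom, or to the Cα of any mutation position, is at
    most ``radius``.  Prolines and glycines are never selected by
    distance (no rotatable side chain to sample).
    """
    mut_lookup: dict[tuple[str, int], list[str]] = {}
    mut_ca = []
    for m in mutation_positions:
        key = (str(m["chain"]), int(m["resid"]))
        try:
            idx = scaffold.index_of(*key)
        except KeyError:
            raise KeyError(f"mutation position {key[0]}{key[1]} not found in scaffold") from None
        mut_lookup[key] = [str(a).upper() for a in m.get("mutations", [])]
        mut_ca.append(scaffold.residues[idx].atom("CA").coords)
    mut_ca_arr = np.array(mut_ca).reshape(-1, 3)
    lig_heavy = np.array([a.coords for a in ligand.atoms if not a.is_hydrogen]).reshape(-1, 3)
    targets = np.vstack([lig_heavy, mut_ca_arr]) if mut_ca else lig_heavy

    positions: list[DesignPosition] = []
    for res in scaffold.residues:
        key = (res.chain, res.seq_id)
        if key in mut_lookup:
            native = res.aa
            allowed = [native] + [a for a in mut_lookup[key] if a != native]
            positions.append(
                DesignPosition(chain=res.chain, seq_id=res.seq_id, allowed_aas=allowed, is_mutable=True)
            )
            continue
        if res.aa in ("PRO", "GLY"):
            continue
        sc = _sidechain_heavy_coords(res)
        if sc.size == 0:
            continue
        if cdist(sc, targets).min() <= radius:
            positions.append(
                DesignPosition(chain=res.chain, seq_id=res.seq_id, allowed_aas=[res.aa])
            )
    if apply_static:
        positions = apply_static_rules(positions, scaffold)
    return positions


def _disulfide_residues(scaffold: Scaffold) -> set[tuple[str, int]]:
    cys = [
        (r.chain, r.seq_id, r.atom("SG").coords)
        for r in scaffold.residues
        if r.aa == "CYS" and r.has_atom("SG")
    ]
    bridged: set[tuple[str, int]] = set()
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            if np.linalg.norm(cys[i][2] - cys[j][2]) <= DISULFIDE_SG_MAX:
                bridged.add(cys[i][:2])
                bridged.add(cys[j][:2])
    return bridged


def apply_static_rules(
    positions: list[DesignPosition], scaffold: Scaffold
) -> list[DesignPosition]:
    """Remove segment-terminal and disulfide-bridged positions.

    A requested mutation position that falls under a static rule is a
    hard error rather than a silent drop.
    """
    bridged = _disulfide_residues(scaffold)
    kept: list[DesignPosition] = []
    for pos in positions:
        idx = scaffold.index_of(pos.chain, pos.seq_id)
        static = scaffold.is_segment_terminus(idx) or (pos.chain, pos.seq_id) in bridged
        if static and pos.is_mutable:
            raise ValueError(
                f"mutation position {pos.chain}{pos.seq_id} is static "
                "(segment terminus or disulfide bridge)"
            )
        if not static:
            kept.append(pos)
    return kept


def build_pocket(scaffold: Scaffold, positions: list[DesignPosition]) -> PocketModel:
    """Split the scaffold into the fixed part and per-position variable groups.

    Design positions keep their backbone atoms in the fixed scaffold;
    side-chain atoms (beyond Cα, including side-chain hydrogens) are
    stripped and returned as the native variable groups.
    """
    design_keys = {(p.chain, p.seq_id) for p in positions}
    for p in positions:
        scaffold.index_of(p.chain, p.seq_id)  # existence check

    fixed_residues: list[Residue] = []
    native_sidechains: list[list[Atom]] = [[] for _ in positions]
    pos_order = {(p.chain, p.seq_id): i for i, p in enumerate(positions)}
    for res in scaffold.residues:
        key = (res.chain, res.seq_id)
        if key in design_keys:
            bb = [a for a in res.atoms if a.name in BACKBONE_NAMES]
            native_sidechains[pos_order[key]] = [
                copy.deepcopy(a) for a in res.atoms if a.name not in BACKBONE_NAMES
            ]
            fixed_residues.append(
                Residue(chain=res.chain, seq_id=res.seq_id, aa=res.aa, atoms=[copy.deepcopy(a) for a in bb])
            )
        else:
            fixed_residues.append(
                Residue(chain=res.chain, seq_id=res.seq_id, aa=res.aa, atoms=[copy.deepcopy(a) for a in res.atoms])
            )
    fixed = Scaffold(residues=fixed_residues, segment_breaks=list(scaffold.segment_breaks))
    return PocketModel(
        scaffold=scaffold,
        positions=list(positions),
        fixed_scaffold=fixed,
        position_indices=[scaffold.index_of(p.chain, p.seq_id) for p in positions],
        native_sidechains=native_sidechains,
    )
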