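"""Rotamer construction from a chi-angle library and scaffold-clash pruning.

Side chains are rebuilt from ideal-geometry templates: the template is
attached at the residue's N/CA/C backbone frame and every chi torsion is
set exactly during NeRF placement, so re-measuring a chi reproduces the
requested value to machine precision.  No rotamer minimisation is applied
— clash relief is delegated entirely to the vdW pruning step, which keeps
a rotamer only if its Lennard-Jones energy against the fixed scaffold is
below a threshold (default 100 kcal/mol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .energy import (
    AtomBlock,
    lj_interaction,
    rotamer_scaffold_exclusions,
    _scaffold_label_index,
)
from .geometry import dihedral, place_atom
from .model import Atom, ForceFieldParams, RotamerLibrary, Scaffold
from .templates import CHI_ATOMS, CHI_COUNT, RESIDUE_TEMPLATES

__all__ = [
    "Rotamer",
    "RotamerSet",
    "backbone_dihedrals",
    "build_rotamers",
    "build_rotamer_set",
    "prune_by_scaffold_vdw",
    "measure_chis",
]


@dataclass
class Rotamer:
    position_index: int
    aa: str
    chis: tuple[float, ...]
    atoms: list[Atom]
    source_prob: float = 1.0


@dataclass
class RotamerSet:
    """Per-position rotamer candidates with pruning bookkeeping.

    ``rotamers[p]`` lists every built rotamer; after pruning, ``kept[p]``
    flags survivors and ``scaffold_vdw[p]`` holds the pruning energies.
    Kept order preserves build order, so indices into the kept list are
    stable.
    """

    positions: list
    rotamers: list[list[Rotamer]]
    kept: list[np.ndarray] = field(default_factory=list)
    scaffold_vdw: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.kept:
            self.kept = [np.ones(len(r), dtype=bool) for r in self.rotamers]
        if not self.scaffold_vdw:
            self.scaffold_vdw = [np.full(len(r), np.nan) for r in self.rotamers]

    def kept_rotamers(self) -> list[list[Rotamer]]:
        return [
            [r for r, k in zip(rots, kept) if k]
            for rots, kept in zip(self.rotamers, self.kept)
        ]

    @property
    def n_kept(self) -> list[int]:
        return [int(k.sum()) for k in self.kept]


def backbone_dihedrals(scaffold: Scaffold, res_index: int) -> tuple[float, float]:
    """Backbone (phi, psi) in degrees for a non-terminal residue.

    phi = C'(i-1)-N-CA-C, psi = N-CA-C-N'(i+1), both in (-180, 180].
    """
    prev, nxt = scaffold.neighbors(res_index)
    if prev is None or nxt is None:
        raise ValueError(
            f"residue index {res_index}: phi/psi undefined at a segment terminus"
        )
    res = scaffold.residues[res_index]
    phi = dihedral(
        scaffold.residues[prev].atom("C").coords,
        res.atom("N").coords,
        res.atom("CA").coords,
        res.atom("C").coords,
    )
    psi = dihedral(
        res.atom("N").coords,
        res.atom("CA").coords,
        res.atom("C").coords,
        scaffold.residues[nxt].atom("N").coords,
    )
    return phi, psi


def _build_sidechain(
    res, aa: str, chis: tuple[float, ...], params: ForceFieldParams
) -> list[Atom]:
    """Place template atoms onto the residue's backbone frame."""
    coords: dict[str, np.ndarray] = {
        "N": res.atom("N").coords,
        "CA": res.atom("CA").coords,
        "C": res.atom("C").coords,
    }
    atoms: list[Atom] = []
    for name, element, refs, bond, angle, tor in RESIDUE_TEMPLATES[aa]:
        if isinstance(tor, tuple):
            _, k, offset = tor
            torsion = chis[k - 1] + offset
        else:
            torsion = tor
        xyz = place_atom(coords[refs[0]], coords[refs[1]], coords[refs[2]], bond, angle, torsion)
        coords[name] = xyz
        atom = Atom(name=name, element=element, coords=xyz, vdw_radius=1.0)
        row = params.scaffold_row(aa, name)
        atom.charge = row["charge"]
        atom.lj_rmin_half = row["rmin_half"]
        atom.lj_epsilon = row["epsilon"]
        atom.vdw_radius = row["vdw_radius"]
        atom.atom_class = row["atom_class"]
        atoms.append(atom)
    return atoms


def build_rotamers(
    scaffold: Scaffold,
    res_index: int,
    aa: str,
    library: RotamerLibrary,
    params: ForceFieldParams,
    position_index: int = 0,
) -> list[Rotamer]:
    """All library rotamers of ``aa`` at a scaffold position.

    Amino acids without rotatable side-chain dihedrals (GLY, ALA) yield a
    single rotamer independent of the library.  An amino acid absent from
    the library's backbone bin yields an empty list with a warning.
    """
    aa = aa.upper()
    if aa == "PRO":
        raise ValueError("proline side chains are not sampled")
    if aa not in RESIDUE_TEMPLATES:
        raise KeyError(f"no geometry template for amino acid {aa!r}")
    res = scaffold.residues[res_index]

    if CHI_COUNT[aa] == 0:
        atoms = _build_sidechain(res, aa, (), params)
        return [Rotamer(position_index=position_index, aa=aa, chis=(), atoms=atoms)]

    # backbone-independent (wildcard) entries need no phi/psi
    if (aa, "*", "*") in library.entries:
        entries = library.entries[(aa, "*", "*")]
    else:
        phi, psi = backbone_dihedrals(scaffold, res_index)
        entries = library.lookup(aa, phi, psi)
    if not entries:
        warnings.warn(f"library has no {aa} rotamers for residue index {res_index}")
        return []
    rotamers = []
    for chis, prob in entries:
        atoms = _build_sidechain(res, aa, chis, params)
        rotamers.append(
            Rotamer(position_index=position_index, aa=aa, chis=chis, atoms=atoms, source_prob=prob)
        )
    return rotamers


def build_rotamer_set(
    pocket,
    library: RotamerLibrary,
    params: ForceFieldParams,
    include_native: bool = False,
) -> RotamerSet:
    """Rotamers for every design position, concatenated over allowed aas.

    With ``include_native=True`` the crystal-native side chain (stripped
    during pocket partitioning) is prepended as an extra candidate.
    """
    per_position: list[list[Rotamer]] = []
    for p, pos in enumerate(pocket.positions):
        res_index = pocket.position_indices[p]
        rots: list[Rotamer] = []
        if include_native and pocket.native_sidechains[p]:
            native_aa = pocket.scaffold.residues[res_index].aa
            rots.append(
                Rotamer(
                    position_index=p,
                    aa=native_aa,
                    chis=measure_chis(native_aa, pocket.scaffold.residues[res_index]),
                    atoms=[a.moved_to(a.coords) for a in pocket.native_sidechains[p]],
                )
            )
        for aa in pos.allowed_aas:
            if aa.upper() == "GLY":
                rots.append(Rotamer(position_index=p, aa="GLY", chis=(), atoms=[]))
                continue
            rots.extend(
                build_rotamers(pocket.scaffold, res_index, aa, library, params, position_index=p)
            )
        if not rots:
            raise ValueError(f"position {pos.chain}{pos.seq_id} has no rotamers")
        per_position.append(rots)
    return RotamerSet(positions=list(pocket.positions), rotamers=per_position)


def measure_chis(aa: str, residue_or_atoms) -> tuple[float, ...]:
    """Measure chi dihedrals from built coordinates (degrees)."""
    if hasattr(residue_or_atoms, "atoms"):
        atom_map = {a.name: a.coords for a in residue_or_atoms.atoms}
    else:
        atom_map = {a.name: a.coords for a in residue_or_atoms}
    chis = []
    for quad in CHI_ATOMS[aa.upper()]:
        try:
            pts = [atom_map[name] for name in quad]
        except KeyError:
            break
        chis.append(dihedral(*pts))
    return tuple(chis)


def prune_by_scaffold_vdw(
    rotamer_set: RotamerSet,
    pocket,
    params: ForceFieldParams,
    threshold: float = 100.0,
) -> RotamerSet:
    """Keep rotamers whose scaffold Lennard-Jones energy is below threshold.

    A pure filter: kept = {rotamer : LJ(rotamer, fixed scaffold) <
    threshold}, with the bonded exclusions of the rotamer's own residue
    applied.  Empty positions after pruning are a hard error (the solver
    requires at least one candidate everywhere).
    """
    scaffold_block = AtomBlock.from_atoms(pocket.fixed_scaffold.atoms)
    for p, rots in enumerate(rotamer_set.rotamers):
        energies = np.empty(len(rots))
        for i, rot in enumerate(rots):
            if not rot.atoms:
                energies[i] = 0.0  # glycine-style empty group
                continue
            labels = _scaffold_label_index(pocket, pocket.position_indices[p])
            excl = rotamer_scaffold_exclusions(rot.aa, [a.name for a in rot.atoms], labels)
            energies[i] = lj_interaction(rot.atoms, scaffold_block, params, excl)
        rotamer_set.scaffold_vdw[p] = energies
        rotamer_set.kept[p] = energies < threshold
        if not rotamer_set.kept[p].any():
            pos = rotamer_set.positions[p]
            raise ValueError(
                f"position {pos.chain}{pos.seq_id} has no viable rotamers "
                f"(all {len(rots)} candidates at or above {threshold} kcal/mol)"
            )
    return rotamer_set
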