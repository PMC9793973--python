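"""Ligand pose-grid expansion and scaffold-clash pruning.

Each input conformer is rigidly rotated and translated over a systematic
grid (defaults: ±20° about each axis, ±0.5 Å along each direction, one
step per side, i.e. 3 values per axis and 729 poses per conformer).
Rotations are intrinsic about the conformer's heavy-atom centroid in
fixed axis order x→y→z, followed by the translation; every transform is
rigid, so intra-ligand distances are preserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .energy import AtomBlock, lj_interaction
from .model import Atom, ForceFieldParams, LigandConformer
from .geometry import euler_rotation_matrix

__all__ = ["Pose", "PoseSet", "axis_values", "generate_pose_grid", "prune_poses"]


@dataclass
class Pose:
    conformer_id: int
    rot: tuple[float, float, float]
    trans: tuple[float, float, float]
    atoms: list[Atom]

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms]).reshape(-1, 3)


@dataclass
class PoseSet:
    poses: list[Pose]
    kept: np.ndarray = field(default=None)
    scaffold_vdw: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.kept is None:
            self.kept = np.ones(len(self.poses), dtype=bool)
        if self.scaffold_vdw is None:
            self.scaffold_vdw = np.full(len(self.poses), np.nan)

    def kept_poses(self) -> list[Pose]:
        return [p for p, k in zip(self.poses, self.kept) if k]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


def axis_values(max_value: float, step: float) -> list[float]:
    """Per-axis sample values {-max, ..., 0, ..., +max}, always including 0.

    Built outward from 0 in units of ``step``; the extremes ±max are
    always included (when ``step`` divides ``max`` this is exactly the
    arithmetic grid from -max to +max).  ``step > max`` collapses the
    axis to the single value 0, with a warning.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if max_value < 0:
        raise ValueError("max must be non-negative")
    if max_value == 0:
        return [0.0]
    if step > max_value:
        warnings.warn(f"step {step} exceeds max {max_value}; axis collapsed to 0")
        return [0.0]
    k = int(np.floor(max_value / step + 1e-9))
    vals = [i * step for i in range(-k, k + 1)]
    if k * step < max_value - 1e-9:
        vals = [-max_value] + vals + [max_value]
    return vals


def generate_pose_grid(
    conformers: list[LigandConformer],
    rot_max: float = 20.0,
    rot_step: float = 20.0,
    trans_max: float = 0.5,
    trans_step: float = 0.5,
) -> PoseSet:
    """Expand conformers over the rotation/translation grid.

    Output order is lexicographic in (conformer_id, rot_x, rot_y, rot_z,
    trans_x, trans_y, trans_z), ascending, which makes the ensemble
    deterministic and reproducible.
    """
    rot_vals = axis_values(rot_max, rot_step)
    trans_vals = axis_values(trans_max, trans_step)
    poses: list[Pose] = []
    for conf in conformers:
        centroid = conf.centroid
        base = conf.coords() - centroid
        for rx, ry, rz in product(rot_vals, rot_vals, rot_vals):
            rot_m = euler_rotation_matrix(rx, ry, rz)
            rotated = base @ rot_m.T + centroid
            for tx, ty, tz in product(trans_vals, trans_vals, trans_vals):
                shifted = rotated + np.array([tx, ty, tz])
                atoms = [a.moved_to(c) for a, c in zip(conf.atoms, shifted)]
                poses.append(
                    Pose(
                        conformer_id=conf.conformer_id,
                        rot=(rx, ry, rz),
                        trans=(tx, ty, tz),
                        atoms=atoms,
                    )
                )
    return PoseSet(poses=poses)


def prune_poses(
    pose_set: PoseSet,
    fixed_scaffold,
    params: ForceFieldParams,
    threshold: float = 100.0,
) -> PoseSet:
    """Keep poses with scaffold Lennard-Jones energy below threshold.

    Same contract as rotamer pruning (a pure filter); no bonded
    exclusions apply between ligand and protein.  Zero surviving poses is
    a hard error.
    """
    scaffold_block = AtomBlock.from_atoms(
        fixed_scaffold.atoms if hasattr(fixed_scaffold, "atoms") else fixed_scaffold
    )
    energies = np.array(
        [lj_interaction(p.atoms, scaffold_block, params) for p in pose_set.poses]
    )
    pose_set.scaffold_vdw = energies
    pose_set.kept = energies < threshold
    if not pose_set.kept.any():
        raise ValueError(
            f"no viable ligand poses (all {len(pose_set.poses)} at or above "
            f"{threshold} kcal/mol in the scaffold)"
        )
    return pose_set
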