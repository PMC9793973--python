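"""Staged design pipeline with cached-stage detection.

A design project lives in a directory with a ``config.yaml`` and an
``output/`` tree, one subdirectory per stage::

    pocket -> rotamers -> energies -> solve -> report
            \\-> poses  ->/

Each completed stage writes a ``manifest.json`` carrying a hash of the
stage-relevant configuration, its input files and its upstream stage
hashes.  On re-run a stage is skipped if and only if its manifest hash
matches, so changing e.g. the pruning threshold recomputes pruning and
everything downstream, but nothing upstream.  ``force=True`` ignores all
manifests.

Stage results are stored as plain-text files (JSON/CSV/PDB) so they can
be inspected and diffed; pose coordinates are reconstructed
deterministically from the stored grid transforms rather than persisted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .energy import ScoringWeights, compute_tables, save_tables, load_tables
from .model import (
    Atom,
    read_ligand_conformers,
    read_param_table,
    read_rotamer_library,
    read_scaffold,
)
from .pocket import DesignPosition, build_pocket, select_flexible
from .poses import PoseSet, generate_pose_grid, prune_poses
from .reporting import (
    build_report,
    file_checksum,
    render_report,
    write_design_structure,
)
from .rotamers import Rotamer, RotamerSet, build_rotamer_set, prune_by_scaffold_vdw
from .solver import Solution, enumerate_best

__all__ = ["DesignProject", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "flex_radius": 4.0,
    "vdw_prune_threshold": 100.0,
    "include_native_rotamer": False,
    "rot_max": 20.0,
    "rot_step": 20.0,
    "trans_max": 0.5,
    "trans_step": 0.5,
    "binding_scale": 50.0,
    "n_solutions": 1,
    "weights": {},
}


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


def _atom_to_dict(a: Atom) -> dict:
    return {
        "name": a.name,
        "element": a.element,
        "coords": [float(x) for x in a.coords],
        "charge": a.charge,
        "rmin_half": a.lj_rmin_half,
        "epsilon": a.lj_epsilon,
        "vdw_radius": a.vdw_radius,
        "class": a.atom_class,
    }


def _atom_from_dict(d: dict) -> Atom:
    a = Atom(name=d["name"], element=d["element"], coords=np.array(d["coords"]), vdw_radius=1.0)
    a.charge = d["charge"]
    a.lj_rmin_half = d["rmin_half"]
    a.lj_epsilon = d["epsilon"]
    a.vdw_radius = d["vdw_radius"]
    a.atom_class = d["class"]
    return a


@dataclass
class StageResult:
    name: str
    hash: str
    skipped: bool


class DesignProject:
    """Load a config, run pipeline stages, reuse cached results."""

    def __init__(
        self,
        config_path: str | Path,
        workdir: str | Path | None = None,
        workers: int = 1,
        force: bool = False,
        progress: bool = False,
    ) -> None:
        self.config_path = Path(config_path)
        self.root = self.config_path.parent
        raw = yaml.safe_load(self.config_path.read_text())
        self.config = dict(DEFAULT_CONFIG)
        self.config.update(raw or {})
        self.workdir = Path(workdir) if workdir is not None else self.root / "output"
        self.workers = workers
        self.force = force
        self.progress = progress
        self.stage_log: list[StageResult] = []

        self._scaffold = None
        self._conformers = None
        self._params = None
        self._pocket = None
        self._rotamer_set = None
        self._pose_set = None
        self._tables = None
        self._solutions = None

    # -- inputs -------------------------------------------------------------
    def _path(self, key: str) -> Path:
        return self.root / self.config[key]

    @property
    def scaffold(self):
        if self._scaffold is None:
            self._scaffold = read_scaffold(self._path("scaffold"), self._path("scaffold_params"))
        return self._scaffold

    @property
    def conformers(self):
        if self._conformers is None:
            self._conformers = read_ligand_conformers(
                self._path("ligand"), self._path("ligand_params")
            )
        return self._conformers

    @property
    def params(self):
        if self._params is None:
            self._params = read_param_table(self._path("scaffold_params"))
        return self._params

    @property
    def weights(self) -> ScoringWeights:
        return ScoringWeights(**self.config.get("weights", {}))

    # -- caching ------------------------------------------------------------
    def _stage_dir(self, name: str) -> Path:
        d = self.workdir / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _manifest_ok(self, name: str, stage_hash: str, outputs: list[str]) -> bool:
        if self.force:
            return False
        d = self.workdir / name
        mf = d / "manifest.json"
        if not mf.exists():
            return False
        try:
            recorded = json.loads(mf.read_text())["hash"]
        except (json.JSONDecodeError, KeyError):
            return False
        return recorded == stage_hash and all((d / o).exists() for o in outputs)

    def _write_manifest(self, name: str, stage_hash: str) -> None:
        (self.workdir / name / "manifest.json").write_text(
            json.dumps({"stage": name, "hash": stage_hash}, indent=2, sort_keys=True)
        )

    def _log(self, name: str, stage_hash: str, skipped: bool) -> None:
        self.stage_log.append(StageResult(name=name, hash=stage_hash, skipped=skipped))

    # -- stage hashes -------------------------------------------------------
    def _hash_pocket(self) -> str:
        return _hash_obj(
            {
                "scaffold": file_checksum(self._path("scaffold")),
                "scaffold_params": file_checksum(self._path("scaffold_params")),
                "ligand": file_checksum(self._path("ligand")),
                "positions": self.config["positions"],
                "flex_radius": self.config["flex_radius"],
            }
        )

    def _hash_rotamers(self) -> str:
        return _hash_obj(
            {
                "upstream": self._hash_pocket(),
                "rotamer_lib": file_checksum(self._path("rotamer_lib")),
                "include_native": self.config["include_native_rotamer"],
                "threshold": self.config["vdw_prune_threshold"],
            }
        )

    def _hash_poses(self) -> str:
        return _hash_obj(
            {
                "upstream": self._hash_pocket(),
                "ligand_params": file_checksum(self._path("ligand_params")),
                "grid": [
                    self.config["rot_max"],
                    self.config["rot_step"],
                    self.config["trans_max"],
                    self.config["trans_step"],
                ],
                "threshold": self.config["vdw_prune_threshold"],
            }
        )

    def _hash_energies(self) -> str:
        return _hash_obj(
            {
                "rotamers": self._hash_rotamers(),
                "poses": self._hash_poses(),
                "weights": self.config.get("weights", {}),
                "binding_scale": self.config["binding_scale"],
            }
        )

    def _hash_solve(self) -> str:
        return _hash_obj({"energies": self._hash_energies(), "n": self.config["n_solutions"]})

    # -- stages -------------------------------------------------------------
    def prepare_pocket(self):
        stage_hash = self._hash_pocket()
        d = self._stage_dir("pocket")
        if self._manifest_ok("pocket", stage_hash, ["positions.json"]):
            data = json.loads((d / "positions.json").read_text())
            positions = [
                DesignPosition(
                    chain=e["chain"],
                    seq_id=e["seq_id"],
                    allowed_aas=e["allowed_aas"],
                    is_mutable=e["is_mutable"],
                )
                for e in data
            ]
            self._log("pocket", stage_hash, skipped=True)
        else:
            positions = select_flexible(
                self.scaffold,
                self.conformers[0],
                self.config["positions"],
                radius=self.config["flex_radius"],
            )
            (d / "positions.json").write_text(
                json.dumps(
                    [
                        {
                            "chain": p.chain,
                            "seq_id": p.seq_id,
                            "allowed_aas": p.allowed_aas,
                            "is_mutable": p.is_mutable,
                        }
                        for p in positions
                    ],
                    indent=2,
                    sort_keys=True,
                )
            )
            self._write_manifest("pocket", stage_hash)
            self._log("pocket", stage_hash, skipped=False)
        self._pocket = build_pocket(self.scaffold, positions)
        return self._pocket

    def sample_rotamers(self):
        if self._pocket is None:
            self.prepare_pocket()
        stage_hash = self._hash_rotamers()
        d = self._stage_dir("rotamers")
        if self._manifest_ok("rotamers", stage_hash, ["rotamers.json"]):
            data = json.loads((d / "rotamers.json").read_text())
            rotamers = [
                [
                    Rotamer(
                        position_index=p,
                        aa=e["aa"],
                        chis=tuple(e["chis"]),
                        atoms=[_atom_from_dict(a) for a in e["atoms"]],
                        source_prob=e["prob"],
                    )
                    for e in entries
                ]
                for p, entries in enumerate(data["rotamers"])
            ]
            rset = RotamerSet(positions=self._pocket.positions, rotamers=rotamers)
            rset.kept = [np.array(k, dtype=bool) for k in data["kept"]]
            rset.scaffold_vdw = [np.array(v, dtype=float) for v in data["vdw"]]
            self._log("rotamers", stage_hash, skipped=True)
        else:
            library = read_rotamer_library(self._path("rotamer_lib"))
            rset = build_rotamer_set(
                self._pocket,
                library,
                self.params,
                include_native=self.config["include_native_rotamer"],
            )
            prune_by_scaffold_vdw(
                rset, self._pocket, self.params, threshold=self.config["vdw_prune_threshold"]
            )
            (d / "rotamers.json").write_text(
                json.dumps(
                    {
                        "rotamers": [
                            [
                                {
                                    "aa": r.aa,
                                    "chis": list(r.chis),
                                    "prob": r.source_prob,
                                    "atoms": [_atom_to_dict(a) for a in r.atoms],
                                }
                                for r in rots
                            ]
                            for rots in rset.rotamers
                        ],
                        "kept": [[bool(x) for x in k] for k in rset.kept],
                        "vdw": [[float(x) for x in v] for v in rset.scaffold_vdw],
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
            self._write_manifest("rotamers", stage_hash)
            self._log("rotamers", stage_hash, skipped=False)
        self._rotamer_set = rset
        return rset

    def sample_poses(self):
        if self._pocket is None:
            self.prepare_pocket()
        stage_hash = self._hash_poses()
        d = self._stage_dir("poses")
        cfg = self.config
        pose_set = generate_pose_grid(
            self.conformers,
            rot_max=cfg["rot_max"],
            rot_step=cfg["rot_step"],
            trans_max=cfg["trans_max"],
            trans_step=cfg["trans_step"],
        )
        if self._manifest_ok("poses", stage_hash, ["poses.csv"]):
            rows = np.loadtxt(d / "poses.csv", delimiter=",", skiprows=1).reshape(-1, 3)
            pose_set.kept = rows[:, 1].astype(bool)
            pose_set.scaffold_vdw = rows[:, 2]
            self._log("poses", stage_hash, skipped=True)
        else:
            prune_poses(
                pose_set,
                self._pocket.fixed_scaffold,
                self.params,
                threshold=cfg["vdw_prune_threshold"],
            )
            lines = ["pose,kept,scaffold_vdw"]
            for i, (k, v) in enumerate(zip(pose_set.kept, pose_set.scaffold_vdw)):
                lines.append(f"{i},{int(k)},{v:.17g}")
            (d / "poses.csv").write_text("\n".join(lines) + "\n")
            self._write_manifest("poses", stage_hash)
            self._log("poses", stage_hash, skipped=False)
        self._pose_set = pose_set
        return pose_set

    def compute_energies(self):
        if self._rotamer_set is None:
            self.sample_rotamers()
        if self._pose_set is None:
            self.sample_poses()
        stage_hash = self._hash_energies()
        d = self._stage_dir("energies")
        if self._manifest_ok("energies", stage_hash, ["tables.json"]):
            tables = load_tables(d)
            self._log("energies", stage_hash, skipped=True)
        else:
            tables = compute_tables(
                self._pocket,
                self._rotamer_set,
                self._pose_set,
                params=self.params,
                weights=self.weights,
                binding_scale=self.config["binding_scale"],
                workers=self.workers,
                progress=self.progress,
            )
            save_tables(tables, d, config_hash=stage_hash)
            self._write_manifest("energies", stage_hash)
            self._log("energies", stage_hash, skipped=False)
        self._tables = tables
        return tables

    def solve(self):
        if self._tables is None:
            self.compute_energies()
        stage_hash = self._hash_solve()
        d = self._stage_dir("solve")
        if self._manifest_ok("solve", stage_hash, ["solutions.json"]):
            data = json.loads((d / "solutions.json").read_text())
            solutions = [
                Solution(
                    rotamer_choice=tuple(e["rotamer_choice"]),
                    pose_choice=e["pose_choice"],
                    total_energy=e["total"],
                    packing_energy=e["packing"],
                    binding_energy_raw=e["binding_raw"],
                    binding_energy_scaled=e["binding_scaled"],
                )
                for e in data
            ]
            self._log("solve", stage_hash, skipped=True)
        else:
            solutions = enumerate_best(self._tables, self.config["n_solutions"])
            (d / "solutions.json").write_text(
                json.dumps(
                    [
                        {
                            "rotamer_choice": list(s.rotamer_choice),
                            "pose_choice": s.pose_choice,
                            "total": s.total_energy,
                            "packing": s.packing_energy,
                            "binding_raw": s.binding_energy_raw,
                            "binding_scaled": s.binding_energy_scaled,
                        }
                        for s in solutions
                    ],
                    indent=2,
                    sort_keys=True,
                )
            )
            self._write_manifest("solve", stage_hash)
            self._log("solve", stage_hash, skipped=False)
        self._solutions = solutions
        return solutions

    def report(self):
        if self._solutions is None:
            self.solve()
        d = self._stage_dir("report")
        labels = [f"{p.chain}{p.seq_id}" for p in self._pocket.positions]
        provenance = {
            "config_hash": _hash_obj(self.config),
            "inputs": {
                key: file_checksum(self._path(key))
                for key in ("scaffold", "scaffold_params", "ligand", "ligand_params", "rotamer_lib")
            },
            "stages": {s.name: s.hash for s in self.stage_log},
        }
        report = build_report(
            self._tables,
            self._solutions,
            position_labels=labels,
            rotamer_set=self._rotamer_set,
            provenance=provenance,
        )
        render_report(report, "text", d / "report.txt")
        render_report(report, "html", d / "report.html")
        for i, sol in enumerate(self._solutions):
            write_design_structure(
                self._pocket, sol, self._rotamer_set, self._pose_set, d / f"design_{i}.pdb"
            )
        return report

    def run_all(self):
        """Full pipeline; returns the list of solutions."""
        self.prepare_pocket()
        self.sample_rotamers()
        self.sample_poses()
        self.compute_energies()
        solutions = self.solve()
        self.report()
        return solutions
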