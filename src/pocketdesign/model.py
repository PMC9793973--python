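"""Domain types and file I/O for pocket design.

Units are fixed package-wide: coordinates in Ångström, energies in
kcal/mol, partial charges in elementary charge units, angles in degrees.

The structural types (:class:`Atom`, :class:`Residue`, :class:`Scaffold`,
:class:`LigandConformer`) carry their non-bonded parameters directly, so
that downstream energy code never has to consult a lookup table: parameter
attachment happens once, at read time, and is total — a structure with a
parameterless atom cannot be constructed through the readers.

File formats:

* scaffold — single-model PDB (``ATOM``/``HETATM`` records only);
* ligand conformers — multi-record SDF (V2000) with identical atom order;
* per-atom parameters — TSV with columns
  ``res  atom  charge  rmin_half  epsilon  vdw_radius  class``
  (scaffold rows keyed by residue + atom name, ligand rows by the 0-based
  atom index in the ``atom`` column);
* rotamer library — TSV with columns
  ``aa  phi_bin  psi_bin  prob  chi1 .. chi4``, a ``# bin_width=<deg>``
  header line, and ``*`` wildcard bins for backbone-independent libraries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Residue",
    "Scaffold",
    "LigandConformer",
    "RotamerLibrary",
    "ForceFieldParams",
    "ATOM_CLASSES",
    "BACKBONE_NAMES",
    "read_param_table",
    "read_scaffold",
    "write_scaffold",
    "write_pdb",
    "read_ligand_conformers",
    "read_rotamer_library",
]

ATOM_CLASSES = ("hydrophobic", "hbond_donor", "hbond_acceptor", "none")

#: Atom names treated as backbone (everything else is side chain).
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "H", "HA", "OXT"})

#: Peptide C-N distance (Å) above which consecutive residues are
#: considered to belong to different segments.
PEPTIDE_BOND_MAX = 2.0


@dataclass
class Atom:
    """A point atom with attached non-bonded parameters."""

    name: str
    element: str
    coords: np.ndarray
    charge: float = 0.0
    lj_rmin_half: float = 0.0
    lj_epsilon: float = 0.0
    vdw_radius: float = 0.0
    atom_class: str = "none"
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.name}: lj_epsilon must be >= 0")
        if self.atom_class not in ATOM_CLASSES:
            raise ValueError(f"atom {self.name}: unknown atom class {self.atom_class!r}")
        self.is_hydrogen = self.is_hydrogen or self.element.upper() == "H"
        if not self.is_hydrogen and self.vdw_radius <= 0:
            raise ValueError(f"heavy atom {self.name}: vdw_radius must be > 0")

    def moved_to(self, coords: np.ndarray) -> "Atom":
        """Copy of this atom at new coordinates (parameters shared)."""
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class Residue:
    chain: str
    seq_id: int
    aa: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if sum(1 for a in self.atoms if a.name == "CA") != 1:
            raise ValueError(
                f"residue {self.chain}{self.seq_id} {self.aa}: must contain exactly one CA"
            )

    @property
    def backbone_mask(self) -> np.ndarray:
        return np.array([a.name in BACKBONE_NAMES for a in self.atoms])

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.chain}{self.seq_id} {self.aa}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_NAMES]


@dataclass
class Scaffold:
    """A fixed protein model: ordered residues plus segment boundaries.

    ``segment_breaks`` holds indices ``i`` such that residue ``i`` is the
    last residue of a segment (chain end or broken peptide bond); the final
    residue is always a break.
    """

    residues: list[Residue]
    segment_breaks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.chain, r.seq_id) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, seq_id) in scaffold")
        if self.residues and not self.segment_breaks:
            self.segment_breaks = self._detect_segment_breaks()

    def _detect_segment_breaks(self) -> list[int]:
        breaks = []
        for i in range(len(self.residues) - 1):
            r, nxt = self.residues[i], self.residues[i + 1]
            if r.chain != nxt.chain:
                breaks.append(i)
                continue
            try:
                d = float(np.linalg.norm(nxt.atom("N").coords - r.atom("C").coords))
            except KeyError:
                breaks.append(i)
                continue
            if d > PEPTIDE_BOND_MAX:
                breaks.append(i)
        breaks.append(len(self.residues) - 1)
        return breaks

    def index_of(self, chain: str, seq_id: int) -> int:
        for i, r in enumerate(self.residues):
            if r.chain == chain and r.seq_id == seq_id:
                return i
        raise KeyError(f"no residue {chain}{seq_id} in scaffold")

    def is_segment_terminus(self, index: int) -> bool:
        """True for the first or last residue of any segment."""
        if index == 0 or index in self.segment_breaks:
            return True
        return (index - 1) in self.segment_breaks

    def neighbors(self, index: int) -> tuple[int | None, int | None]:
        """Indices of the bonded previous/next residues, or None at termini."""
        prev = index - 1 if index > 0 and (index - 1) not in self.segment_breaks else None
        nxt = index + 1 if index not in self.segment_breaks else None
        if nxt is not None and nxt >= len(self.residues):
            nxt = None
        return prev, nxt

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms]).reshape(-1, 3)


@dataclass
class LigandConformer:
    conformer_id: int
    atoms: list[Atom]

    @property
    def centroid(self) -> np.ndarray:
        """Arithmetic mean of heavy-atom coordinates."""
        heavy = [a.coords for a in self.atoms if not a.is_hydrogen]
        return np.mean(np.array(heavy), axis=0)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms]).reshape(-1, 3)


@dataclass
class RotamerLibrary:
    """Backbone-dependent chi-angle library.

    ``entries`` maps ``(aa, phi_bin, psi_bin)`` to a list of
    ``(chis, probability)`` tuples, where bins are the bin-center values
    declared in the file or ``"*"`` for backbone-independent wildcards.
    """

    entries: dict[tuple[str, float | str, float | str], list[tuple[tuple[float, ...], float]]]
    bin_width: float

    def _nearest_bin(self, angle: float) -> float:
        """Nearest bin center on the [-180, 180) wheel; ties round toward -180."""
        w = self.bin_width
        # wrap into [-180, 180)
        a = ((angle + 180.0) % 360.0) - 180.0
        lo = math.floor((a + 180.0) / w)
        c_lo = -180.0 + lo * w
        c_hi = c_lo + w
        # tie (exact midpoint) goes to the lower center, i.e. toward -180
        center = c_lo if (a - c_lo) <= (c_hi - a) else c_hi
        if center >= 180.0:
            center -= 360.0
        return center

    def lookup(self, aa: str, phi: float, psi: float) -> list[tuple[tuple[float, ...], float]]:
        wild = (aa, "*", "*")
        if wild in self.entries:
            return self.entries[wild]
        key = (aa, self._nearest_bin(phi), self._nearest_bin(psi))
        return self.entries.get(key, [])

    @property
    def amino_acids(self) -> set[str]:
        return {k[0] for k in self.entries}


@dataclass
class ForceFieldParams:
    """Per-atom non-bonded parameters plus global force-field constants.

    ``scaffold`` is keyed by ``(residue name, atom name)``; ``ligand`` by
    the 0-based atom index of the conformer records.  The 1-4 scale
    factors follow the AMBER convention (LJ 0.5, Coulomb 1/1.2) and apply
    only across the three-bond pairs at the CA/CB cut of a rotamer's own
    residue.
    """

    scaffold: dict[tuple[str, str], dict] = field(default_factory=dict)
    ligand: dict[int, dict] = field(default_factory=dict)
    coulomb_constant: float = 332.0636
    lj_14_scale: float = 0.5
    coulomb_14_scale: float = 1.0 / 1.2

    def scaffold_row(self, res_name: str, atom_name: str) -> dict:
        try:
            return self.scaffold[(res_name, atom_name)]
        except KeyError:
            raise KeyError(
                f"no parameter row for residue {res_name!r} atom {atom_name!r}"
            ) from None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PARAM_COLUMNS = ["res", "atom", "charge", "rmin_half", "epsilon", "vdw_radius", "class"]


def read_param_table(path: str | Path, ligand: bool = False) -> ForceFieldParams:
    """Read a per-atom parameter TSV.

    With ``ligand=True`` the ``atom`` column is interpreted as the 0-based
    atom index of the conformer records and rows are keyed by that index.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"res": str, "atom": str})
    missing = [c for c in _PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"parameter table {path}: missing columns {missing}")
    params = ForceFieldParams()
    for _, row in df.iterrows():
        cls = str(row["class"])
        if cls not in ATOM_CLASSES:
            raise ValueError(f"parameter table {path}: unknown atom class {cls!r}")
        entry = {
            "charge": float(row["charge"]),
            "rmin_half": float(row["rmin_half"]),
            "epsilon": float(row["epsilon"]),
            "vdw_radius": float(row["vdw_radius"]),
            "atom_class": cls,
        }
        if ligand:
            params.ligand[int(row["atom"])] = entry
        else:
            key = (str(row["res"]), str(row["atom"]))
            if key in params.scaffold:
                raise ValueError(f"parameter table {path}: duplicate row for {key}")
            params.scaffold[key] = entry
    return params


def _attach(atom: Atom, entry: dict) -> None:
    atom.charge = entry["charge"]
    atom.lj_rmin_half = entry["rmin_half"]
    atom.lj_epsilon = entry["epsilon"]
    atom.vdw_radius = entry["vdw_radius"]
    atom.atom_class = entry["atom_class"]


def parameterize_atom(atom: Atom, params: ForceFieldParams, res_name: str) -> Atom:
    """Return ``atom`` with scaffold parameters for ``res_name`` attached."""
    _attach(atom, params.scaffold_row(res_name, atom.name))
    return atom


def read_scaffold(pdb_path: str | Path, param_path: str | Path) -> Scaffold:
    """Read a single-model protein PDB and attach per-atom parameters.

    Only ``ATOM``/``HETATM`` records are considered.  Alternate locations
    are resolved to the highest occupancy (ties: first encountered);
    insertion codes are rejected; a multi-model file is a hard error.
    """
    pdb = PDBFile.read(str(pdb_path))
    if pdb.get_model_count() != 1:
        raise ValueError(f"{pdb_path}: expected a single-model PDB, found {pdb.get_model_count()} models")
    arr = pdb.get_structure(model=1, altloc="all", extra_fields=["occupancy"])
    if np.any(arr.ins_code != ""):
        bad = arr.ins_code[arr.ins_code != ""][0]
        raise ValueError(f"{pdb_path}: insertion codes are not supported (found {bad!r})")

    # resolve altlocs: per (chain, res_id, atom name) keep the highest
    # occupancy; exact occupancy ties keep the first record encountered
    keep = np.ones(arr.array_length(), dtype=bool)
    seen: dict[tuple, int] = {}
    for i in range(arr.array_length()):
        key = (arr.chain_id[i], int(arr.res_id[i]), arr.atom_name[i])
        if key not in seen:
            seen[key] = i
        else:
            j = seen[key]
            if arr.occupancy[i] > arr.occupancy[j]:
                keep[j] = False
                seen[key] = i
            else:
                keep[i] = False
    arr = arr[keep]

    params = read_param_table(param_path)
    residues: list[Residue] = []
    current_key = None
    current_atoms: list[Atom] = []
    current_meta = None

    def flush() -> None:
        if current_meta is not None:
            chain, seq_id, aa = current_meta
            residues.append(Residue(chain=chain, seq_id=seq_id, aa=aa, atoms=list(current_atoms)))

    for i in range(arr.array_length()):
        key = (arr.chain_id[i], int(arr.res_id[i]))
        if key != current_key:
            flush()
            current_key = key
            current_atoms = []
            current_meta = (arr.chain_id[i], int(arr.res_id[i]), arr.res_name[i])
        name = arr.atom_name[i]
        element = arr.element[i] if arr.element[i] else name[0]
        atom = Atom(name=name, element=element, coords=arr.coord[i], vdw_radius=1.0)
        try:
            _attach(atom, params.scaffold_row(arr.res_name[i], name))
        except KeyError:
            raise KeyError(
                f"{pdb_path}: no parameter row for residue "
                f"{arr.res_name[i]} {arr.chain_id[i]}{int(arr.res_id[i])}, atom {name}"
            ) from None
        current_atoms.append(atom)
    flush()
    return Scaffold(residues=residues)


def _to_atom_array(
    residues: list[tuple[str, int, str, list[Atom], bool]],
) -> struc.AtomArray:
    """Build a biotite AtomArray from (chain, seq_id, res_name, atoms, hetero) tuples."""
    n = sum(len(atoms) for *_, atoms, _ in residues)
    arr = struc.AtomArray(n)
    i = 0
    for chain, seq_id, res_name, atoms, hetero in residues:
        for a in atoms:
            arr.coord[i] = a.coords
            arr.chain_id[i] = chain
            arr.res_id[i] = seq_id
            arr.res_name[i] = res_name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
            arr.hetero[i] = hetero
            i += 1
    return arr


def write_pdb(
    path: str | Path,
    residues: list[tuple[str, int, str, list[Atom], bool]],
) -> None:
    """Write residue tuples ``(chain, seq_id, res_name, atoms, hetero)`` as PDB."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(residues))
    pdb.write(str(path))


def write_scaffold(scaffold: Scaffold, path: str | Path) -> None:
    write_pdb(path, [(r.chain, r.seq_id, r.aa, r.atoms, False) for r in scaffold.residues])


def write_model_ensemble(
    path: str | Path,
    models: list[list[tuple[str, int, str, list[Atom], bool]]],
) -> None:
    """Write a multi-MODEL PDB (one MODEL block per entry of ``models``)."""
    arrays = [_to_atom_array(m) for m in models]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_ligand_conformers(sdf_path: str | Path, param_path: str | Path) -> list[LigandConformer]:
    """Read a multi-record SDF into conformers with shared parameters.

    All records must describe the same molecule: identical atom count and
    element order (the conformers differ only in coordinates).
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(sdf_path), sanitize=False, removeHs=False)
    params = read_param_table(param_path, ligand=True)
    conformers: list[LigandConformer] = []
    ref_elements: list[str] | None = None
    for rec_idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{sdf_path}: record {rec_idx} could not be parsed")
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        if ref_elements is None:
            ref_elements = elements
        elif elements != ref_elements:
            raise ValueError(
                f"{sdf_path}: record {rec_idx} atom graph differs from record 0 "
                f"({len(elements)} atoms vs {len(ref_elements)})"
            )
        conf = mol.GetConformer()
        atoms = []
        for i, el in enumerate(elements):
            if i not in params.ligand:
                raise KeyError(f"{param_path}: no parameter row for ligand atom index {i}")
            pos = conf.GetAtomPosition(i)
            atom = Atom(
                name=f"{el}{i + 1}",
                element=el,
                coords=np.array([pos.x, pos.y, pos.z]),
                vdw_radius=1.0,
            )
            _attach(atom, params.ligand[i])
            atoms.append(atom)
        conformers.append(LigandConformer(conformer_id=rec_idx, atoms=atoms))
    if not conformers:
        raise ValueError(f"{sdf_path}: no conformer records")
    return conformers


def read_rotamer_library(tsv_path: str | Path) -> RotamerLibrary:
    """Read a chi-angle rotamer library TSV.

    The first non-empty line must be a ``# bin_width=<degrees>`` header.
    ``phi_bin``/``psi_bin`` are bin-center values or ``*`` wildcards.
    The per-key probabilities must sum to at most 1 (within 1e-6), and the
    chi count of every row must match the amino acid's number of rotatable
    side-chain dihedrals.
    """
    from .templates import CHI_COUNT

    path = Path(tsv_path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].lstrip().startswith("#"):
        raise ValueError(f"{tsv_path}: missing '# bin_width=' header line")
    header = lines[0].lstrip("# ").strip()
    if "=" not in header or not header.startswith("bin_width"):
        raise ValueError(f"{tsv_path}: first line must declare bin_width")
    bin_width = float(header.split("=", 1)[1])
    if bin_width <= 0:
        raise ValueError(f"{tsv_path}: bin_width must be positive")

    cols = lines[1].split("\t")
    expected_prefix = ["aa", "phi_bin", "psi_bin", "prob"]
    if cols[: len(expected_prefix)] != expected_prefix:
        raise ValueError(f"{tsv_path}: column header must start with {expected_prefix}")

    entries: dict = {}
    for ln in lines[2:]:
        fields = ln.split("\t")
        aa = fields[0].strip()
        phi_s, psi_s = fields[1].strip(), fields[2].strip()
        prob = float(fields[3])
        chis = tuple(float(x) for x in fields[4:] if x.strip() not in ("", "-"))
        if aa not in CHI_COUNT:
            raise ValueError(f"{tsv_path}: unsupported amino acid {aa!r}")
        if len(chis) != CHI_COUNT[aa]:
            raise ValueError(
                f"{tsv_path}: {aa} row has {len(chis)} chi values, expected {CHI_COUNT[aa]}"
            )
        phi_bin: float | str = "*" if phi_s == "*" else float(phi_s)
        psi_bin: float | str = "*" if psi_s == "*" else float(psi_s)
        if (phi_bin == "*") != (psi_bin == "*"):
            raise ValueError(f"{tsv_path}: phi and psi wildcards must be used together")
        entries.setdefault((aa, phi_bin, psi_bin), []).append((chis, prob))

    for key, rows in entries.items():
        total = sum(p for _, p in rows)
        if total > 1.0 + 1e-6:
            raise ValueError(
                f"{tsv_path}: probabilities for {key} sum to {total:.6f} > 1"
            )
    return RotamerLibrary(entries=entries, bin_width=bin_width)
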