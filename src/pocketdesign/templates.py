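"""Ideal side-chain geometry templates.

Each template lists heavy side-chain atoms in buildable order.  An atom is
placed from three previously known reference atoms by NeRF construction
(bond length to the third reference, bond angle at it, torsion across all
three).  Torsions are either fixed numbers (ring closure, branch offsets)
or ``("chi", k, offset)`` — the torsion equals the requested k-th chi
angle plus a constant branch offset, so setting chi values during rotamer
construction is exact by construction.

Bond lengths and angles are generic ideal values (sp3 C-C 1.53 Å /
109.5-110.5°, carbonyl/carboxylate C-O 1.25 Å / 120°, aromatic C-C
1.39 Å / 120°, C-S 1.81 Å).  Rebuilt side chains are heavy-atom only; in
the toy parameterisations used throughout, hydrogen contributions are
folded into the heavy-atom parameters (united-atom style).

The backbone reference atoms N, CA, C come from the scaffold; CB is
placed off the backbone with the standard L-amino-acid improper torsion
N-C-CA-CB = -122.7°.
"""

from __future__ import annotations

__all__ = ["RESIDUE_TEMPLATES", "CHI_ATOMS", "CHI_COUNT", "sidechain_bonds"]

# torsion spec: float (fixed) or ("chi", k, offset_deg)
# record: (name, element, (ref_a, ref_b, ref_c), bond, angle, torsion)

_CB = ("CB", "C", ("N", "C", "CA"), 1.53, 110.5, -122.7)

RESIDUE_TEMPLATES: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [
        _CB,
        ("OG", "O", ("N", "CA", "CB"), 1.42, 110.5, ("chi", 1, 0.0)),
    ],
    "CYS": [
        _CB,
        ("SG", "S", ("N", "CA", "CB"), 1.81, 113.8, ("chi", 1, 0.0)),
    ],
    "THR": [
        _CB,
        ("OG1", "O", ("N", "CA", "CB"), 1.42, 110.5, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 1, -120.0)),
    ],
    "VAL": [
        _CB,
        ("CG1", "C", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 1, 120.0)),
    ],
    "LEU": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.53, 110.5, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.53, 110.5, ("chi", 2, 120.0)),
    ],
    "ILE": [
        _CB,
        ("CG1", "C", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 1, -120.0)),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.53, 110.5, ("chi", 2, 0.0)),
    ],
    "ASP": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0.0)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2, 0.0)),
        ("OD2", "O", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2, 180.0)),
    ],
    "ASN": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0.0)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.23, 120.8, ("chi", 2, 0.0)),
        ("ND2", "N", ("CA", "CB", "CG"), 1.33, 116.4, ("chi", 2, 180.0)),
    ],
    "MET": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.53, 114.1, ("chi", 1, 0.0)),
        ("SD", "S", ("CA", "CB", "CG"), 1.81, 112.7, ("chi", 2, 0.0)),
        ("CE", "C", ("CB", "CG", "SD"), 1.79, 100.2, ("chi", 3, 0.0)),
    ],
    "GLU": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.53, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.25, 118.4, ("chi", 3, 0.0)),
        ("OE2", "O", ("CB", "CG", "CD"), 1.25, 118.4, ("chi", 3, 180.0)),
    ],
    "LYS": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.53, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.53, 111.3, ("chi", 2, 0.0)),
        ("CE", "C", ("CB", "CG", "CD"), 1.53, 111.3, ("chi", 3, 0.0)),
        ("NZ", "N", ("CG", "CD", "CE"), 1.49, 111.9, ("chi", 4, 0.0)),
    ],
    "PHE": [
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.51, 113.8, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
}

#: Chi dihedral atom quadruples (IUPAC), in chi order.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "LYS": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [],  # ring residue: recognised but never sampled
}

CHI_COUNT: dict[str, int] = {aa: len(chis) for aa, chis in CHI_ATOMS.items()}


def sidechain_bonds(aa: str) -> list[tuple[str, str]]:
    """Covalent bonds within the side chain, plus the CA-CB attachment.

    Derived from the template build order: every placed atom is bonded to
    its third reference atom.  Ring-closing bonds (PHE CE1-CZ style) are
    implied by geometry but irrelevant for 1-2/1-3/1-4 exclusion search
    toward the backbone, which only crosses the CA-CB cut.
    """
    bonds = []
    for rec in RESIDUE_TEMPLATES.get(aa, []):
        name, _el, refs, *_ = rec
        bonds.append((refs[2], name))
    return bonds
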