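"""Rigid-body and internal-coordinate geometry primitives.

All coordinates are in Ångström, all angles in degrees. These helpers are
shared by the rotamer builder (NeRF atom placement, dihedral measurement),
the pose sampler (Euler rotations about a centroid) and the RMSD operator
(Kabsch superposition).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "bond_angle",
    "place_atom",
    "euler_rotation_matrix",
    "kabsch",
    "rmsd",
    "superpose",
]


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion angle a-b-c-d in degrees, in (-180, 180].

    Uses the atan2 formulation, which is numerically stable near 0 and 180.
    Sign follows the IUPAC convention: looking from b to c, a clockwise
    rotation of d relative to a is positive.
    """
    b1 = np.asarray(b, float) - np.asarray(a, float)
    b2 = np.asarray(c, float) - np.asarray(b, float)
    b3 = np.asarray(d, float) - np.asarray(c, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place a new atom D given three reference atoms (NeRF construction).

    D is positioned so that |C-D| = ``bond``, the angle B-C-D equals
    ``angle`` (degrees) and the torsion A-B-C-D equals ``torsion``
    (degrees).  The construction is exact: re-measuring the internal
    coordinates of the returned point reproduces the inputs to machine
    precision.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    ang = np.radians(angle)
    tor = np.radians(torsion)

    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)

    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def euler_rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix for intrinsic rotations about x, then y, then z.

    Angles in degrees. The composed matrix is ``Rz @ Ry @ Rx`` acting on
    column vectors.
    """
    ax, ay, az = np.radians([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx_m = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry_m = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz_m = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz_m @ ry_m @ rx_m


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimises the RMSD
    to ``reference`` over proper rotations (reflections are excluded by
    the determinant correction).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    return rot, trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation of two matched coordinate sets (Å)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(
    mobile_fit: np.ndarray,
    reference_fit: np.ndarray,
    mobile_apply: np.ndarray,
) -> np.ndarray:
    """Fit ``mobile_fit`` onto ``reference_fit`` and transform ``mobile_apply``."""
    rot, trans = kabsch(mobile_fit, reference_fit)
    return np.asarray(mobile_apply, float) @ rot.T + trans
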