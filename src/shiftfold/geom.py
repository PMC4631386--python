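"""Small 3D geometry utilities: internal-coordinate atom placement,
Kabsch superposition, RMSD."""

from __future__ import annotations

import numpy as np


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom D given positions of A, B, C and internal coordinates
    (|C-D| = bond, angle(B,C,D) = `angle`, dihedral(A,B,C,D) = `dihedral`;
    angles in degrees). The natural-extension-reference-frame construction.
    """
    angle = np.deg2rad(angle)
    dihedral = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def kabsch_rotation(mobile: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Optimal proper rotation matrix aligning centred `mobile` onto
    centred `fixed` (both (n, 3), already centred)."""
    h = mobile.T @ fixed
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    return u @ diag @ vt


def superpose(mobile: np.ndarray, fixed: np.ndarray,
              apply_to: np.ndarray | None = None) -> np.ndarray:
    """Least-squares superpose `mobile` onto `fixed`; returns the
    transformed copy of `apply_to` (default: of `mobile`)."""
    if apply_to is None:
        apply_to = mobile
    mc = mobile.mean(axis=0)
    fc = fixed.mean(axis=0)
    rot = kabsch_rotation(mobile - mc, fixed - fc)
    return (apply_to - mc) @ rot + fc


def rmsd(a: np.ndarray, b: np.ndarray, superposed: bool = False) -> float:
    """RMSD between coordinate sets; optimally superposes first unless
    `superposed` is True."""
    if not superposed:
        a = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
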