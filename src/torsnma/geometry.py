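"""Small vector-geometry kernel shared by the builders and the NMA engine.

Conventions: dihedral angles follow the IUPAC sign convention (right-handed
about the central bond, range (-180, 180] degrees when converted); Kabsch
superposition returns a proper rotation (det = +1).
"""

from __future__ import annotations

import numpy as np


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in radians."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Torsion angle a-b-c-d in radians, IUPAC sign convention."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(-np.dot(m, n2), np.dot(n1, n2)))


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, theta: float, phi: float,
) -> np.ndarray:
    """NeRF placement: position D bonded to c with |cD| = bond,
    angle(b, c, D) = theta and dihedral(a, b, c, D) = phi (radians)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-10:
        raise ValueError("collinear reference atoms in internal-coordinate placement")
    n /= norm_n
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rotation matrix about a (non-unit) axis by theta radians (Rodrigues)."""
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("zero-length rotation axis")
    k = axis / norm
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (R, t, rmsd) such that ``mobile @ R.T + t`` minimizes the RMSD to
    ``target`` over all proper rigid transforms.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superposition requires two equally shaped (n, 3) arrays")
    if mobile.shape[0] < 3:
        raise ValueError("superposition requires at least 3 paired atoms")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd
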