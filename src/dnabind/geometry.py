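"""Small 3D geometry helpers: superposition, internal coordinates, rotations."""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation R, translation t) such that ``mobile @ R.T + t``
    optimally matches ``target`` (both (n, 3), n >= 3 non-collinear).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    r = vt.T @ s @ u.T
    return r, ct - r @ cm


def apply_rigid(coords: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ r.T + t


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in radians."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral a-b-c-d in radians, IUPAC sign convention."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, theta: float, phi: float,
) -> np.ndarray:
    """NeRF placement: position of atom d given chain a-b-c and internal coords.

    ``bond`` is |c-d|, ``theta`` the angle b-c-d (radians), ``phi`` the
    dihedral a-b-c-d (radians).
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        # a-b-c nearly collinear: pick an arbitrary perpendicular
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-10:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(phi),
        -bond * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a (unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    cc = 1.0 - c
    return np.array([
        [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
        [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
        [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
    ])
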