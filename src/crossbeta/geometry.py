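"""Internal geometry helpers: NeRF atom placement, dihedrals, rigid transforms.

All coordinates are in Angstroms. These are pure functions on numpy arrays;
nothing here knows about residues or chains.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "dihedral",
    "bond_angle",
    "rotation_about_axis",
    "kabsch_frame",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    bond_angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place atom D bonded to ``c`` using the NeRF construction.

    D is positioned so that \\|c-D\\| = *bond_length*, the angle b-c-D equals
    *bond_angle_deg* and the dihedral a-b-c-D equals *dihedral_deg*.
    """
    theta = np.deg2rad(bond_angle_deg)
    chi = np.deg2rad(dihedral_deg)

    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)

    d_local = bond_length * np.array(
        [
            -np.cos(theta),
            np.sin(theta) * np.cos(chi),
            np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.rad2deg(np.arctan2(y, x)))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = _unit(np.asarray(p0) - np.asarray(p1))
    v = _unit(np.asarray(p2) - np.asarray(p1))
    return float(np.rad2deg(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix about ``axis`` through the origin (Rodrigues)."""
    k = _unit(np.asarray(axis, dtype=float))
    t = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def kabsch_frame(ca_xyz: np.ndarray, carbonyl_dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Canonical strand frame from Calpha coordinates and C=O directions.

    Returns ``(origin, R)`` such that ``(xyz - origin) @ R.T`` puts the strand
    centroid at the origin, the N->C strand axis along +x and the mean
    alternating carbonyl direction along +y (the hydrogen-bonding direction
    of an extended strand); side chains then spread along +-z.
    """
    ca = np.asarray(ca_xyz, dtype=float)
    origin = ca.mean(axis=0)
    x = _unit(ca[-1] - ca[0])
    signs = np.array([(-1.0) ** i for i in range(len(carbonyl_dirs))])
    ymix = (signs[:, None] * carbonyl_dirs).mean(axis=0)
    y = ymix - np.dot(ymix, x) * x
    if np.linalg.norm(y) < 1e-9:  # degenerate (e.g. helix): pick any normal
        y = np.cross(x, [0.0, 0.0, 1.0])
        if np.linalg.norm(y) < 1e-9:
            y = np.cross(x, [0.0, 1.0, 0.0])
    y = _unit(y)
    z = np.cross(x, y)
    R = np.vstack([x, y, z])
    return origin, R
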