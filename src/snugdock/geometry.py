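"""Low-level vector geometry shared across the package.

Torsion measurement, internal-coordinate atom placement (NeRF), axis-angle
rotations and least-squares (Kabsch) superposition.  All angles at this layer
are in degrees unless a name says otherwise; coordinates are in Angstrom.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

# Idealized peptide geometry (Engh-Huber-like values).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize near-zero vector")
    return v / n


def measure_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = normalize(a - b)
    v = normalize(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def measure_dihedral(a, b, c, d) -> float:
    """Signed dihedral angle a-b-c-d in degrees, in (-180, 180]."""
    b0 = a - b
    b1 = c - b
    b2 = d - c
    b1n = normalize(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = normalize(c - b)
    n = normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix for a right-handed rotation about ``axis``
    (Rodrigues form)."""
    u = normalize(np.asarray(axis, dtype=float))
    theta = np.radians(angle_deg)
    K = np.array([[0.0, -u[2], u[1]], [u[2], 0.0, -u[0]], [-u[1], u[0], 0.0]])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def rotate_points_about_line(
    points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float
) -> np.ndarray:
    R = rotation_about_axis(axis, angle_deg)
    return (points - origin) @ R.T + origin


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    while np.linalg.norm(v) < 1e-8:
        v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rotation+translation mapping ``mobile`` onto ``target``.

    Returns (R, t) with ``mobile @ R.T + t`` optimally superposed, using the
    determinant-corrected closed-form solution.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - mc @ R.T
    return R, t


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    R, t = kabsch_rotation(mobile, target)
    return mobile @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superposed_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    return rmsd(superpose(mobile, target), target)
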