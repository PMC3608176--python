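"""Low-level 3-D geometry helpers shared across the package.

Internal-coordinate atom placement (the NeRF construction), dihedral
measurement, and rotation utilities used by the move set, the loop-closure
machinery and the synthetic-bundle builders.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def unit(v: np.ndarray) -> np.ndarray:
    """Return v normalised to unit length; raises on a near-zero vector."""
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a zero-length vector")
    return v / n


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place atom D given three upstream atoms A-B-C and internal coordinates.

    The returned point satisfies |D-C| = bond, angle(B,C,D) = angle_deg and
    dihedral(A,B,C,D) = dihedral_deg (IUPAC sign convention).
    """
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p1 - p0
    b1 = unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    u = unit(p0 - p1)
    v = unit(p2 - p1)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix for a right-handed rotation about a unit axis."""
    return Rotation.from_rotvec(unit(axis) * np.deg2rad(angle_deg)).as_matrix()


def rotate_points(
    points: np.ndarray, rot: np.ndarray, center: np.ndarray
) -> np.ndarray:
    """Rotate an (..., 3) array of points about ``center`` by matrix ``rot``."""
    return (points - center) @ rot.T + center


def perpendicular_vector(v: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """A unit vector perpendicular to v.

    Deterministic when ``rng`` is None; otherwise the in-plane direction is
    drawn from ``rng`` (used to break the tie when a rotation axis is
    geometrically undefined).
    """
    v = unit(v)
    seed_dir = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed_dir, v)) > 0.9:
        seed_dir = np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(v, seed_dir))
    if rng is None:
        return e1
    e2 = np.cross(v, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(phi) * e1 + np.sin(phi) * e2
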