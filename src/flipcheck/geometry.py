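"""Exact 3D geometry primitives: distances, angles, torsions, chiral volumes,
rigid superposition and internal-coordinate atom placement.

Conventions
-----------
* Points are length-3 numpy arrays (Å).
* All angles are in degrees.
* Torsions follow the IUPAC sign convention (clockwise positive looking
  from the second to the third atom) and live in (−180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "distance",
    "bond_angle",
    "dihedral_angle",
    "chiral_volume",
    "vector_angle",
    "superpose",
    "apply_transform",
    "rotation_about_axis",
    "place_atom",
    "wrap_angle",
]


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite coordinates")
    return a


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into (−180, 180]."""
    a = float(deg) % 360.0
    if a > 180.0:
        a -= 360.0
    # map −180 exactly to +180 so the range is half-open
    if a <= -180.0:
        a += 360.0
    return a


def distance(a, b) -> float:
    """Euclidean distance |a−b| in Å."""
    return float(np.linalg.norm(_as_point(a) - _as_point(b)))


def bond_angle(a, vertex, c) -> float:
    """Angle a–vertex–c in degrees, in [0, 180]."""
    v = _as_point(vertex)
    u1 = _as_point(a) - v
    u2 = _as_point(c) - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("degenerate angle: zero-length arm")
    cosang = np.clip(np.dot(u1, u2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def vector_angle(u, v) -> float:
    """Angle between two direction vectors in degrees [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("zero vector")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion p1–p2–p3–p4 in degrees, range (−180, 180].

    IUPAC convention: looking from p2 towards p3, the far bond rotating
    clockwise from the near bond gives a positive angle.  Reversing the
    atom order leaves the value unchanged.
    """
    p1, p2, p3, p4 = (_as_point(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise ValueError("undefined torsion: coincident axis atoms")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("undefined torsion: collinear triple")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def chiral_volume(center, a, b, c) -> float:
    """Signed scalar triple product (a−center)·((b−center)×(c−center)), Å³.

    The sign encodes the handedness of the substituent order (a, b, c)
    about the centre; swapping any two substituents flips it.
    """
    ctr = _as_point(center)
    return float(
        np.dot(
            _as_point(a) - ctr,
            np.cross(_as_point(b) - ctr, _as_point(c) - ctr),
        )
    )


def superpose(moving, reference):
    """Least-squares rigid superposition (Kabsch) of point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``points @ rotation.T + translation`` maps *moving* onto *reference*.
    Reflections are excluded; degenerate (collinear or <3 point) inputs
    are rejected.
    """
    mv = np.asarray(moving, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mv.shape != ref.shape or mv.ndim != 2 or mv.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if mv.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    cm = mv.mean(axis=0)
    cr = ref.mean(axis=0)
    x = mv - cm
    y = ref - cr
    # collinearity check: rank of the centred reference set
    if np.linalg.matrix_rank(x, tol=1e-8) < 2 or np.linalg.matrix_rank(y, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cr - rot @ cm
    moved = x @ rot.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(points, rotation, translation) -> np.ndarray:
    """Apply a rigid transform to an (n, 3) array or a single point."""
    pts = np.asarray(points, dtype=float)
    return pts @ np.asarray(rotation).T + np.asarray(translation)


def rotation_about_axis(origin, axis, angle_deg: float):
    """Rotation by *angle_deg* about the line through *origin* along *axis*.

    Returns a callable mapping points (single or (n,3)) to rotated points.
    """
    o = _as_point(origin)
    ax = np.asarray(axis, dtype=float)
    n = np.linalg.norm(ax)
    if n < 1e-12:
        raise ValueError("zero rotation axis")
    k = ax / n
    theta = np.radians(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    kmat = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) * c + s * kmat + (1 - c) * np.outer(k, k)

    def _apply(points):
        pts = np.asarray(points, dtype=float)
        return (pts - o) @ rot.T + o

    return _apply


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |c−d| = *bond*, angle(b,c,d) = *angle* and
    dihedral(a,b,c,d) = *torsion* (degrees).  Standard internal-coordinate
    (NeRF-style) construction used by the synthetic builder.
    """
    a, b, c = (_as_point(p) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms for placement")
    n /= nn
    m = np.cross(n, bc)
    # local displacement: along −bc for angle 180
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
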