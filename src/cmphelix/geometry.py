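"""Elementary vector geometry: distances, angles, dihedrals and the
internal-coordinate (NeRF-style) atom placement used by the helix builder.

All angles are in degrees. Dihedrals follow the IUPAC right-hand sign
convention and are reported in the half-open interval [-180, 180).
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

_EPS = 1e-10


def wrap_angle(angle_deg: float) -> float:
    """Wrap an angle in degrees into [-180, 180)."""
    return float((angle_deg + 180.0) % 360.0 - 180.0)


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees, in [0, 180]."""
    v1 = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    v2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < _EPS or n2 < _EPS:
        raise GeometryError("coincident points: bond angle undefined")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle of the bond p2-p3, IUPAC convention, degrees in [-180, 180).

    Raises :class:`GeometryError` when consecutive points coincide or three
    consecutive points are collinear (the angle is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < _EPS:
            raise GeometryError("coincident consecutive points: dihedral undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise GeometryError("collinear points: dihedral undefined")
    b2u = b2 / np.linalg.norm(b2)
    m1 = np.cross(n1, b2u)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    # IUPAC right-hand rule: positive when the far bond is rotated clockwise
    # relative to the near bond, viewed along the central bond
    return wrap_angle(-np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to C.

    D is placed such that |C-D| = ``length``, the angle B-C-D equals
    ``angle_deg`` and the dihedral A-B-C-D equals ``torsion_deg``.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < _EPS:
        raise GeometryError("coincident B and C: cannot place atom")
    bc = bc / nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        raise GeometryError("collinear A, B, C: cannot place atom")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * np.cos(ang),
            length * np.sin(ang) * np.cos(tor),
            length * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix (3x3) about ``axis`` by ``angle_deg`` (right-handed)."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    ux, uy, uz = u
    cross = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * cross + (1 - c) * np.outer(u, u)
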