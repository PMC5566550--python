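"""Cartesian / internal-coordinate geometry primitives.

Conventions used throughout the package:

* all angles are in **degrees** at every public interface;
* signed dihedral angles live in the half-open interval ``(-180, 180]``
  and follow the IUPAC sign convention (sighting down the central bond
  b->c, the angle is positive when the far bond c->d is rotated
  clockwise from the near bond b->a);
* coordinates are in angstroms.

All functions broadcast over leading axes, so a single call can measure
one geometry or a whole trajectory of frames at once.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize_angle",
    "distance",
    "bond_angle",
    "dihedral",
    "nerf_place",
    "triad_frame",
    "DihedralUndefinedError",
]

_COLLINEAR_TOL = 1e-8


class DihedralUndefinedError(ValueError):
    """Raised when three consecutive atoms of a torsion are collinear."""


def normalize_angle(angle):
    """Map an angle in degrees onto the interval ``(-180, 180]``."""
    a = np.asarray(angle, dtype=float)
    out = 180.0 - np.mod(180.0 - a, 360.0)
    if out.ndim == 0:
        return float(out)
    return out


def _unit(v, *, tol=_COLLINEAR_TOL, context="vector"):
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norm < tol):
        raise DihedralUndefinedError(f"degenerate {context}: zero-length vector")
    return v / norm


def distance(a, b):
    """Euclidean distance between two points (or broadcast point arrays)."""
    d = np.linalg.norm(np.asarray(b, dtype=float) - np.asarray(a, dtype=float), axis=-1)
    if d.ndim == 0:
        return float(d)
    return d


def bond_angle(a, b, c):
    """Angle a-b-c in degrees, in ``[0, 180]``."""
    u = _unit(np.asarray(a, float) - np.asarray(b, float), context="bond angle arm")
    v = _unit(np.asarray(c, float) - np.asarray(b, float), context="bond angle arm")
    cosang = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    if ang.ndim == 0:
        return float(ang)
    return ang


def dihedral(p0, p1, p2, p3):
    """Signed dihedral p0-p1-p2-p3 in degrees, in ``(-180, 180]``.

    Computed with the two-plane atan2 formulation; raises
    :class:`DihedralUndefinedError` when either atom triple is collinear
    (the torsion is then geometrically undefined).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    for n in (n1, n2):
        if np.any(np.linalg.norm(n, axis=-1) < _COLLINEAR_TOL):
            raise DihedralUndefinedError("collinear atoms: dihedral undefined")
    b2u = _unit(b2, context="central bond")
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2u, axis=-1)
    return normalize_angle(np.degrees(np.arctan2(y, x)))


def nerf_place(a, b, c, dist, angle, torsion):
    """Place atom *d* from three reference atoms and internal coordinates.

    Natural extension reference frame (NeRF) construction: *d* is bonded
    to *c* at ``dist`` angstroms, with bond angle b-c-d equal to ``angle``
    degrees and dihedral a-b-c-d equal to ``torsion`` degrees (same sign
    convention as :func:`dihedral`, so the two functions round-trip).

    All arguments broadcast; scalar internals with ``(F, 3)`` reference
    arrays place one atom per frame.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    dist = np.asarray(dist, dtype=float)[..., None]
    theta = np.radians(np.asarray(angle, dtype=float))[..., None]
    phi = np.radians(np.asarray(torsion, dtype=float))[..., None]

    bc = _unit(c - b, context="reference bond b-c")
    n = _unit(np.cross(b - a, bc), context="reference plane a-b-c")
    m = np.cross(n, bc)
    d = c + dist * (-np.cos(theta) * bc + np.sin(theta) * (np.cos(phi) * m + np.sin(phi) * n))
    return d


def triad_frame(p0, p1, p2):
    """Right-handed orthonormal frame spanned by three non-collinear points.

    Returns an array of shape ``(..., 3, 3)`` whose columns are the basis
    vectors: e1 along p0->p1, e2 the in-plane component of p0->p2, e3
    their cross product.  Used for exact rigid-body superposition of
    template fragments onto placed anchor atoms.
    """
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    e1 = _unit(p1 - p0, context="frame axis")
    v = p2 - p0
    v = v - np.sum(v * e1, axis=-1, keepdims=True) * e1
    e2 = _unit(v, context="frame plane")
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=-1)


def tetrahedral_completions(center, nb1, nb2, angle=109.47122):
    """The two unit directions completing a tetrahedral center.

    Given a center atom and unit-independent positions of two bonded
    neighbours, return the pair of unit vectors from the center that make
    ``angle`` degrees with both existing bonds.  The first entry is the
    solution along ``+(nb1-center) x (nb2-center)``, the second the mirror
    solution; callers assign axial/equatorial identity.
    """
    center = np.asarray(center, float)
    a = _unit(np.asarray(nb1, float) - center, context="tetrahedral neighbour")
    b = _unit(np.asarray(nb2, float) - center, context="tetrahedral neighbour")
    cos_t = np.cos(np.radians(angle))
    ab = np.sum(a * b, axis=-1, keepdims=True)
    p = cos_t / (1.0 + ab)
    base = p * (a + b)
    n = _unit(np.cross(a, b), context="tetrahedral plane")
    q_sq = 1.0 - np.sum(base * base, axis=-1, keepdims=True)
    if np.any(q_sq < 0):
        raise ValueError("no tetrahedral completion exists for this neighbour geometry")
    q = np.sqrt(q_sq)
    return base + q * n, base - q * n
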