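"""Low-level vector geometry: dihedrals, internal-coordinate placement,
rigid transforms and weighted superposition.

All coordinates are in Angstrom, all angles in degrees unless noted.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError, InputError

__all__ = [
    "angle_between",
    "dihedral",
    "nerf_place",
    "rotation_about_axis",
    "weighted_superposition",
    "apply_transform",
    "rmsd",
]


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product for plain 3-vectors (much faster than np.cross)."""
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def angle_between(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180].

    Uses the atan2 formulation, which is stable near 0 and 180 degrees.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = _cross3(b0, b1)
    n2 = _cross3(b1, b2)
    m1 = _cross3(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def dihedrals(p0, p1, p2, p3) -> np.ndarray:
    """Vectorized :func:`dihedral` over stacked (n, 3) arrays."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.einsum("...i,...i", n1, n2)
    y = np.einsum("...i,...i", m1, n2)
    return np.degrees(np.arctan2(y, x))


def nerf_place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given reference atoms A, B, C and internal coordinates.

    The new atom is at distance ``bond`` from C, with bond angle B-C-D equal
    to ``angle`` and dihedral A-B-C-D equal to ``torsion`` (degrees).  This is
    the standard natural-extension reference frame construction.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = _cross3(b - a, bc)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-10:
        raise GeometryError("collinear reference atoms in internal-coordinate placement")
    n /= norm_n
    m = _cross3(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues formula)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(t) * k + (1.0 - np.cos(t)) * (k @ k)


def weighted_superposition(mobile, target, weights=None):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Minimizes ``sum_k w_k |R x_k + t - y_k|^2`` over proper rotations R and
    translations t (weighted Kabsch algorithm).

    Parameters
    ----------
    mobile, target : (n, 3) arrays with n >= 3.
    weights : (n,) positive array, optional.  Uniform if omitted.

    Returns
    -------
    (R, t, wrmsd) where ``R`` is a proper rotation (det +1), ``t`` a
    translation and ``wrmsd = sqrt(sum w d^2 / sum w)`` after the transform.
    """
    x = np.asarray(mobile, float)
    y = np.asarray(target, float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise InputError(f"point sets must both be (n, 3); got {x.shape} and {y.shape}")
    n = x.shape[0]
    if n < 3:
        raise InputError("superposition needs at least 3 point pairs")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,):
            raise InputError("weights must match the number of point pairs")
        if np.any(w <= 0):
            raise InputError("superposition weights must be positive")
    wsum = w.sum()
    xc = (w[:, None] * x).sum(0) / wsum
    yc = (w[:, None] * y).sum(0) / wsum
    xm = x - xc
    ym = y - yc
    h = (w[:, None] * xm).T @ ym
    # rank < 2 means the points cannot pin down a rotation
    if np.linalg.matrix_rank(h, tol=1e-9) < 2:
        raise GeometryError("degenerate (collinear or coincident) point sets")
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    rot = vt.T @ s @ u.T
    trans = yc - rot @ xc
    diff = (x @ rot.T + trans) - y
    wrmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum() / wsum))
    return rot, trans, wrmsd


def apply_transform(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    """Apply a rigid transform to an (n, 3) coordinate array."""
    return np.asarray(coords, float) @ np.asarray(rot).T + np.asarray(trans)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unweighted, unfitted) RMSD between matching coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = a - b
    return float(np.sqrt(np.einsum("ij,ij->i", d, d).mean()))
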