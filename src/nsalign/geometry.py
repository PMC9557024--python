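"""Rigid-body superposition primitives.

Least-squares superposition uses the SVD form of the Kabsch algorithm with
the determinant correction that excludes reflections, so the returned
rotation is always proper.
"""

from __future__ import annotations

import numpy as np

from .core import Transform

__all__ = ["kabsch", "rmsd", "apply_transform"]


def _as_points(x) -> np.ndarray:
    pts = np.asarray(x, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (N, 3) coordinate array")
    return pts


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    w = np.cross(u, v)
    s = float(np.linalg.norm(w))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    wx = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + wx + wx @ wx * ((1 - c) / s**2)


def kabsch(points_a, points_b) -> Transform:
    """Proper rotation + translation minimizing RMSD of A mapped onto B.

    For N >= 3 this is the SVD Kabsch solution with the sign of the smallest
    singular value flipped when the raw solution would be a reflection.
    Degenerate sizes keep a documented contract: N == 1 is an exact
    translation; N == 2 aligns the segment direction and matches centroids.
    """
    a, b = _as_points(points_a), _as_points(points_b)
    if a.shape != b.shape:
        raise ValueError("point sets differ in shape")
    n = len(a)
    if n == 0:
        raise ValueError("cannot superpose empty point sets")
    if n == 1:
        return Transform(np.eye(3), b[0] - a[0])
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    if n == 2:
        da, db = a[1] - a[0], b[1] - b[0]
        na, nb = np.linalg.norm(da), np.linalg.norm(db)
        if na < 1e-12 or nb < 1e-12:
            rot = np.eye(3)
        else:
            rot = _rotation_between(da / na, db / nb)
        return Transform(rot, cb - rot @ ca)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return Transform(rot, cb - rot @ ca)


def rmsd(points_a, points_b) -> float:
    """Root-mean-square deviation between paired point sets, in Angstrom."""
    a, b = _as_points(points_a), _as_points(points_b)
    if a.shape != b.shape:
        raise ValueError("point sets differ in shape")
    if len(a) == 0:
        raise ValueError("RMSD of empty point sets is undefined")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def apply_transform(transform: Transform, points) -> np.ndarray:
    """Return ``R x + t`` for every point."""
    return transform.apply(_as_points(points))
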