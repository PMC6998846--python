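"""Chunked vectorized ray/triangle casting (Moller-Trumbore).

Used for shell-thickness measurements where we need the first hit of a ray
launched from a face centroid.  Brute force over triangles, chunked so peak
memory stays modest; adequate for the mesh sizes this package produces.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def first_hit_distances(
    origins: np.ndarray,
    directions: np.ndarray,
    triangles: np.ndarray,
    t_min: float = 1e-6,
    pair_budget: int = 4_000_000,
) -> np.ndarray:
    """First positive hit distance per ray against a triangle soup.

    Parameters
    ----------
    origins, directions : (n, 3) arrays, directions need not be unit
        (distances are reported in units of the direction norm; callers pass
        unit vectors).
    triangles : (m, 3, 3) vertex coordinates.
    t_min : hits closer than this are discarded (the origin's own face).

    Returns ``inf`` where a ray hits nothing.
    """
    origins = np.asarray(origins, dtype=np.float64)
    directions = np.asarray(directions, dtype=np.float64)
    triangles = np.asarray(triangles, dtype=np.float64)
    n = len(origins)
    m = len(triangles)
    if n == 0 or m == 0:
        return np.full(n, np.inf)

    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0

    out = np.full(n, np.inf)
    chunk = max(1, pair_budget // m)
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        o = origins[lo:hi, None, :]          # (c, 1, 3)
        d = directions[lo:hi, None, :]
        p = np.cross(d, e2[None, :, :])      # (c, m, 3)
        det = np.einsum("cmk,mk->cm", p, e1)
        valid = np.abs(det) > _EPS
        inv_det = np.where(valid, 1.0 / np.where(valid, det, 1.0), 0.0)
        s = o - v0[None, :, :]
        u = np.einsum("cmk,cmk->cm", s, p) * inv_det
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("cmk,cmk->cm", q, np.broadcast_to(d, q.shape)) * inv_det
        t = np.einsum("cmk,mk->cm", q, e2) * inv_det
        hit = valid & (u >= -_EPS) & (v >= -_EPS) & (u + v <= 1.0 + _EPS) & (t > t_min)
        t = np.where(hit, t, np.inf)
        out[lo:hi] = t.min(axis=1)
    return out
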