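"""Trilinear interpolation on regular voxel grids.

A small hand-rolled gather keeps the hot paths (plane quadrature, pathline
integration) vectorized over arbitrary leading axes of the value array,
which ``scipy.interpolate.RegularGridInterpolator`` does not support without
one interpolator per frame and component.
"""

from __future__ import annotations

import numpy as np


def trilinear(values: np.ndarray, origin, voxel_size, points: np.ndarray,
              fill: float = 0.0) -> np.ndarray:
    """Interpolate ``values`` (..., nx, ny, nz) at physical ``points`` (m, 3).

    ``origin`` is the center of voxel (0, 0, 0) in mm, ``voxel_size`` the
    spacing per axis in mm.  Points outside the grid get ``fill``.
    Returns an array of shape (..., m).
    """
    values = np.asarray(values)
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    origin = np.asarray(origin, dtype=np.float64)
    voxel = np.asarray(voxel_size, dtype=np.float64)
    shape = np.array(values.shape[-3:])

    f = (points - origin) / voxel          # fractional voxel index
    inside = np.all((f >= 0.0) & (f <= shape - 1), axis=1)
    f = np.clip(f, 0.0, shape - 1)
    i0 = np.minimum(f.astype(np.int64), shape - 2)
    i0 = np.maximum(i0, 0)
    w = f - i0                              # (m, 3) in [0, 1]

    # degenerate axes (single-slice grids): collapse the weight
    for ax in range(3):
        if shape[ax] == 1:
            i0[:, ax] = 0
            w[:, ax] = 0.0

    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    wx, wy, wz = w[:, 0], w[:, 1], w[:, 2]
    sx = 1 if shape[0] > 1 else 0
    sy = 1 if shape[1] > 1 else 0
    sz = 1 if shape[2] > 1 else 0

    out = np.zeros(values.shape[:-3] + (len(points),), dtype=np.float64)
    for dx, cx in ((0, 1.0 - wx), (sx, wx)):
        for dy, cy in ((0, 1.0 - wy), (sy, wy)):
            for dz, cz in ((0, 1.0 - wz), (sz, wz)):
                coeff = cx * cy * cz
                if dx == sx and sx == 0 and dx != 0:
                    continue
                out += coeff * values[..., ix + dx, iy + dy, iz + dz]
    if fill == 0.0:
        out *= inside
    else:
        out = np.where(inside, out, fill)
    return out
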