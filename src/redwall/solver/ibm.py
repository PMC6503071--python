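"""Continuous-forcing immersed-boundary coupling (Peskin 4-point kernel).

Membrane nodal forces are spread to the staggered grid as a body-force
density, and grid velocities are interpolated back to the membrane nodes
with the same kernel, so the two operations are exact adjoints: total force
is conserved and the kernel's moment conditions make interpolation exact on
globally linear velocity fields.
"""

from __future__ import annotations

import numpy as np

from .grid import EulerianGrid, UM, face_offsets


def peskin4(r: np.ndarray) -> np.ndarray:
    """Standard Peskin 4-point kernel (support |r| < 2).

    Satisfies the partition of unity, the even-odd condition and the first
    moment condition exactly, for every shift.
    """
    a = np.abs(r)
    out = np.zeros_like(a)
    m1 = a <= 1.0
    out[m1] = (3.0 - 2.0 * a[m1] + np.sqrt(1.0 + 4.0 * a[m1] - 4.0 * a[m1] ** 2)) / 8.0
    m2 = (a > 1.0) & (a < 2.0)
    out[m2] = (5.0 - 2.0 * a[m2] - np.sqrt(-7.0 + 12.0 * a[m2] - 4.0 * a[m2] ** 2)) / 8.0
    return out


def _kernel_stencil(grid: EulerianGrid, c: int, points_um: np.ndarray):
    """Indices (k=64) and weights of the 4x4x4 kernel cloud per point."""
    s = grid.face_shape(c)
    off = face_offsets(c)
    g = (points_um - grid.origin) / grid.h - off
    base = np.floor(g).astype(int) - 1
    offs = np.arange(4)
    wx = peskin4(g[:, 0, None] - (base[:, 0, None] + offs))
    wy = peskin4(g[:, 1, None] - (base[:, 1, None] + offs))
    wz = peskin4(g[:, 2, None] - (base[:, 2, None] + offs))
    w = (wx[:, :, None, None] * wy[:, None, :, None]
         * wz[:, None, None, :]).reshape(len(points_um), 64)
    ii = (base[:, 0, None] + offs)[:, :, None, None]
    jj = (base[:, 1, None] + offs)[:, None, :, None]
    kk = (base[:, 2, None] + offs)[:, None, None, :]
    ii = np.broadcast_to(ii, (len(points_um), 4, 4, 4)).reshape(-1, 64)
    jj = np.broadcast_to(jj, (len(points_um), 4, 4, 4)).reshape(-1, 64)
    kk = np.broadcast_to(kk, (len(points_um), 4, 4, 4)).reshape(-1, 64)
    if grid.periodic_x:
        ii = ii % s[0]
    else:
        if (ii < 0).any() or (ii >= s[0]).any():
            raise ValueError("membrane point outside the box margin in x")
    if ((jj < 0).any() or (jj >= s[1]).any()
            or (kk < 0).any() or (kk >= s[2]).any()):
        raise ValueError("membrane point outside the box margin")
    return ii, jj, kk, w


def kernel_stencils(grid: EulerianGrid, points_um: np.ndarray) -> list:
    """Compact kernel clouds of all three components: per component the
    (n, 3) base indices plus the three (n, 4) axis weight factors (reused by
    both spreading and interpolation within a time step)."""
    offs = np.arange(4)
    out = []
    for c in range(3):
        s = grid.face_shape(c)
        off = face_offsets(c)
        g = (points_um - grid.origin) / grid.h - off
        base = (np.floor(g) - 1).astype(np.int64)
        w = [peskin4(g[:, ax, None] - (base[:, ax, None] + offs))
             for ax in range(3)]
        if grid.periodic_x:
            lo_ok = (base[:, 1:] >= 0).all()
            hi_ok = (base[:, 1] + 3 < s[1]).all() and (base[:, 2] + 3 < s[2]).all()
        else:
            lo_ok = (base >= 0).all()
            hi_ok = all((base[:, ax] + 3 < s[ax]).all() for ax in range(3))
        if not (lo_ok and hi_ok):
            raise ValueError("membrane point outside the box margin")
        out.append((np.ascontiguousarray(base), w[0], w[1], w[2]))
    return out


def spread_forces(grid: EulerianGrid, points_um: np.ndarray,
                  forces_N: np.ndarray, stencils=None) -> list[np.ndarray]:
    """Spread nodal forces (N) to per-component body-force densities (N/m³)."""
    from ._kernels import spread_points

    if stencils is None:
        stencils = kernel_stencils(grid, points_um)
    h3 = (grid.h * UM) ** 3
    out = []
    for c in range(3):
        base, wx, wy, wz = stencils[c]
        F = np.zeros(grid.face_shape(c))
        spread_points(base, wx, wy, wz,
                      np.ascontiguousarray(forces_N[:, c]) / h3, F,
                      grid.periodic_x)
        out.append(F)
    return out


def interpolate_velocity(grid: EulerianGrid, fields: list[np.ndarray],
                         points_um: np.ndarray, stencils=None) -> np.ndarray:
    """Interpolate grid velocity (m/s) to points with the same kernel."""
    from ._kernels import gather_points

    if stencils is None:
        stencils = kernel_stencils(grid, points_um)
    out = np.empty((len(points_um), 3))
    for c in range(3):
        base, wx, wy, wz = stencils[c]
        out[:, c] = gather_points(base, wx, wy, wz,
                                  np.ascontiguousarray(fields[c]),
                                  grid.periodic_x)
    return out
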