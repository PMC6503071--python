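"""Viscosity indicator field: hemoglobin interior vs plasma exterior.

The cell-interior indicator is a smoothed Heaviside of the signed distance
to each membrane surface (transition half-width w = grid h), evaluated only
inside each cell's bounding box.  The same indicator with weight 1 serves as
the local hematocrit (cell volume fraction) field.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .grid import EulerianGrid

MU_PLASMA = 0.001    # Pa s
MU_INTERIOR = 0.005  # Pa s


def _smoothed_heaviside(d: np.ndarray, w: float) -> np.ndarray:
    """1 deep inside (d << 0), 0 outside, cosine-smoothed over |d| <= w."""
    out = np.zeros_like(d)
    out[d <= -w] = 1.0
    band = np.abs(d) < w
    x = d[band] / w
    out[band] = 0.5 * (1.0 - x - np.sin(np.pi * x) / np.pi)
    return out


def _closed_check(triangles: np.ndarray) -> None:
    und = np.sort(np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]],
                                  triangles[:, [2, 0]]]), axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    if not np.all(counts == 2):
        raise ValueError("open cell surface: indicator field undefined")


def cell_indicator(grid: EulerianGrid, cell_meshes: list[tuple[np.ndarray, np.ndarray]],
                   width_cells: float = 1.0,
                   check_closed: bool = True) -> np.ndarray:
    """Smoothed interior indicator on cell centers; values in [0, 1].

    ``cell_meshes`` is a list of (vertices µm, triangles) closed surfaces.
    Cells may straddle the periodic x boundary (unwrapped coordinates).
    """
    nx, ny, nz = grid.shape
    ind = np.zeros(grid.shape)
    if not cell_meshes:
        return ind
    h = grid.h
    w = width_cells * h
    Lx = grid.box_length[0]
    centers = None
    for verts, tris in cell_meshes:
        if check_closed:
            _closed_check(np.asarray(tris))
        verts = np.asarray(verts, float)
        # vertex normals (area weighted) for the sign of the distance
        tri = verts[tris]
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        vnorm = np.zeros_like(verts)
        for k in range(3):
            np.add.at(vnorm, tris[:, k], fn)
        nlen = np.linalg.norm(vnorm, axis=1, keepdims=True)
        vnorm = vnorm / np.where(nlen == 0, 1.0, nlen)

        shifts = [0.0]
        if grid.periodic_x:
            lo_x, hi_x = verts[:, 0].min(), verts[:, 0].max()
            if lo_x < grid.origin[0] + 2 * h:
                shifts.append(Lx)
            if hi_x > grid.origin[0] + Lx - 2 * h:
                shifts.append(-Lx)
        for sx in shifts:
            v = verts + np.array([sx, 0.0, 0.0])
            lo = np.floor((v.min(axis=0) - (w + 2 * h) - grid.origin) / h - 0.5).astype(int)
            hi = np.ceil((v.max(axis=0) + (w + 2 * h) - grid.origin) / h - 0.5).astype(int)
            lo = np.maximum(lo, 0)
            hi_c = np.minimum(hi, np.array([nx - 1, ny - 1, nz - 1]))
            if np.any(hi_c < lo):
                continue
            sl = tuple(slice(lo[a], hi_c[a] + 1) for a in range(3))
            if centers is None:
                centers = grid.cell_centers()
            pts = centers[sl].reshape(-1, 3)
            tree = cKDTree(v)
            d, nearest = tree.query(pts, k=1)
            sign = np.sign(np.einsum("ij,ij->i", pts - v[nearest],
                                     vnorm[nearest]))
            sign[sign == 0] = 1.0
            vals = _smoothed_heaviside(sign * d, w).reshape(
                tuple(hi_c[a] - lo[a] + 1 for a in range(3)))
            region = ind[sl]
            np.maximum(region, vals, out=region)
    return ind


def viscosity_field(grid: EulerianGrid,
                    cell_meshes: list[tuple[np.ndarray, np.ndarray]],
                    mu_plasma: float = MU_PLASMA,
                    mu_interior: float = MU_INTERIOR) -> np.ndarray:
    """Cell-centered dynamic viscosity (Pa s) with the interior contrast."""
    ind = cell_indicator(grid, cell_meshes)
    return mu_plasma + (mu_interior - mu_plasma) * ind
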