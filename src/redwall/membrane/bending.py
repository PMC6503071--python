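"""Bending resistance: discrete Helfrich energy on the triangulated membrane.

The discrete mean-curvature vector at vertex v is m_v = (L0 x)_v / A_v(x)
with L0 the cotangent Laplacian assembled on the *reference* configuration
and A_v(x) the barycentric vertex area of the *current* one; |m_v|
approximates twice the mean curvature.  The bending energy is

    E_b = (k_b / 2) * sum_v A_v(x) (|m_v| - c0)²

and the nodal forces are its exact gradient in closed form (one sparse
matvec plus a triangle-area-gradient scatter).  Freezing only the cotangent
weights keeps the gradient cheap while the current-area factors preserve
the scale invariance of the Willmore functional (for c0 = 0 the energy of
any sphere is 8 pi k_b, independent of radius); for the near-inextensible
RBC membrane (C_dil >> 1) the metric stays close to the reference, which is
where the frozen weights are exact.
"""

from __future__ import annotations

import numpy as np

from .cell import UM, CellMembrane, ForceDensity


def _vertex_areas(triangles: np.ndarray, x: np.ndarray) -> np.ndarray:
    tri = x[triangles]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(n, axis=1)
    va = np.zeros(len(x))
    np.add.at(va, triangles.ravel(), np.repeat(areas / 3.0, 3))
    return va


def _area_gradient_scatter(triangles: np.ndarray, x: np.ndarray,
                           s: np.ndarray) -> np.ndarray:
    """Gradient of sum_v s_v A_v(x) with barycentric vertex areas."""
    tri = x[triangles]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    nhat = n / np.where(nn == 0, 1.0, nn)
    coef = s[triangles].sum(axis=1) / 3.0
    out = np.zeros_like(x)
    # d(A_T)/d(x_i) = 0.5 * nhat x (opposite edge)
    for k, (a, b) in enumerate(((1, 2), (2, 0), (0, 1))):
        g = 0.5 * np.cross(nhat, tri[:, b] - tri[:, a])
        np.add.at(out, triangles[:, k], coef[:, None] * g)
    return out


def _curvature(L, triangles, x_m: np.ndarray):
    va = _vertex_areas(triangles, x_m)
    m = (L @ x_m) / va[:, None]
    return m, va


def bending_energy(cell: CellMembrane, current_vertices: np.ndarray) -> float:
    """Discrete Helfrich energy (J) at the given positions (µm)."""
    x = np.asarray(current_vertices, float) * UM
    m, va = _curvature(cell.bend_L, cell.triangles, x)
    c0 = cell.c0 / UM
    dev = np.linalg.norm(m, axis=1) - c0
    return float(0.5 * cell.k_b * (va * dev**2).sum())


def bending_forces(cell: CellMembrane, current_vertices: np.ndarray) -> ForceDensity:
    """Nodal bending forces (N): exact negative gradient of the energy."""
    x = np.asarray(current_vertices, float) * UM
    f = _bending_force_arrays(cell, cell.bend_L, cell.triangles, x)
    zeros = np.zeros_like(f)
    return ForceDensity(elastic=zeros, bending=f)


def _bending_force_arrays(cell: CellMembrane, L, triangles,
                          x_m: np.ndarray) -> np.ndarray:
    """Shared kernel (also used for batched multi-cell evaluation)."""
    m, va = _curvature(L, triangles, x_m)
    c0 = cell.c0 / UM
    norm = np.linalg.norm(m, axis=1)
    dev = norm - c0
    with np.errstate(invalid="ignore", divide="ignore"):
        mhat = np.where(norm[:, None] > 0, m / norm[:, None], 0.0)
    f = -cell.k_b * (L @ (dev[:, None] * mhat))
    s = norm**2 - c0**2
    f += 0.5 * cell.k_b * _area_gradient_scatter(triangles, x_m, s)
    return f


def membrane_forces(cell: CellMembrane, current_vertices: np.ndarray) -> ForceDensity:
    """Combined elastic + bending nodal forces (N)."""
    from .skalak import skalak_forces

    fe = skalak_forces(cell, current_vertices)
    fb = bending_forces(cell, current_vertices)
    return ForceDensity(elastic=fe.elastic, bending=fb.bending)
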