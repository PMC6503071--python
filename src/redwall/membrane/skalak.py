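"""In-plane membrane elasticity: Skalak strain-energy law, linear-triangle FEM.

Each triangle carries the strain energy density

    W = (G_s/4) * (I1² + 2 I1 - 2 I2) + (G_s C_dil / 4) * I2²

with in-plane invariants I1 = λ1² + λ2² - 2 and I2 = λ1²λ2² - 1 of the
surface deformation gradient.  Nodal forces are the exact negative gradient
of the total energy with respect to vertex positions, so the membrane is in
equilibrium at the reference shape and invariant under rigid motions.
"""

from __future__ import annotations

import numpy as np

from .cell import UM, CellMembrane, ForceDensity


def _deformation(cell: CellMembrane, current_um: np.ndarray):
    x = np.asarray(current_um, float) * UM
    tri = x[cell.triangles]
    D = np.stack([tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]], axis=2)  # (m,3,2)
    F = D @ cell.ref_inv  # (m, 3, 2)
    G = np.einsum("mki,mkj->mij", F, F)  # right Cauchy-Green, (m, 2, 2)
    detG = G[:, 0, 0] * G[:, 1, 1] - G[:, 0, 1] * G[:, 1, 0]
    return F, G, detG


def skalak_energy(cell: CellMembrane, current_vertices: np.ndarray) -> float:
    """Total elastic energy (J) of the deformed membrane (positions in µm)."""
    _, G, detG = _deformation(cell, current_vertices)
    I1 = G[:, 0, 0] + G[:, 1, 1] - 2.0
    I2 = detG - 1.0
    W = 0.25 * cell.G_s * (I1**2 + 2.0 * I1 - 2.0 * I2) \
        + 0.25 * cell.G_s * cell.C_dil * I2**2
    return float((cell.ref_area * W).sum())


def skalak_forces(cell: CellMembrane, current_vertices: np.ndarray) -> ForceDensity:
    """Nodal elastic forces (N) at the given deformed positions (µm)."""
    if current_vertices.shape != cell.vertices.shape:
        raise ValueError("current vertex array incongruent with the "
                         "triangulation")
    F, G, detG = _deformation(cell, current_vertices)
    bad = np.flatnonzero(detG <= 0)
    if len(bad):
        raise ValueError(f"degenerate deformed triangle id {bad[0]}")
    I1 = G[:, 0, 0] + G[:, 1, 1] - 2.0
    I2 = detG - 1.0
    W1 = 0.5 * cell.G_s * (I1 + 1.0)
    W2 = 0.5 * cell.G_s * (cell.C_dil * I2 - 1.0)
    Ginv = np.empty_like(G)
    Ginv[:, 0, 0] = G[:, 1, 1]
    Ginv[:, 1, 1] = G[:, 0, 0]
    Ginv[:, 0, 1] = -G[:, 0, 1]
    Ginv[:, 1, 0] = -G[:, 1, 0]
    Ginv /= detG[:, None, None]
    # dE/dF per triangle, (m, 3, 2)
    dEdF = cell.ref_area[:, None, None] * (
        2.0 * W1[:, None, None] * F
        + 2.0 * (W2 * detG)[:, None, None] * (F @ Ginv))
    P = dEdF @ np.transpose(cell.ref_inv, (0, 2, 1))  # dE/dD, (m, 3, 2)
    f = np.zeros_like(cell.vertices)
    np.add.at(f, cell.triangles[:, 1], -P[:, :, 0])
    np.add.at(f, cell.triangles[:, 2], -P[:, :, 1])
    np.add.at(f, cell.triangles[:, 0], P[:, :, 0] + P[:, :, 1])
    return ForceDensity(elastic=f, bending=np.zeros_like(f))
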