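"""Red-blood-cell membrane container and surface quadrature.

The membrane is a closed triangulated hyperelastic surface enclosing
hemoglobin solution.  Geometry is stored in µm; elastic and bending force
evaluations return SI newtons per vertex (lumped nodal forces).

Default moduli are standard human-RBC literature values: membrane shear
modulus G_s = 2.5e-6 N/m, Skalak dilation-stiffness ratio C_dil = 100
(near-incompressible membrane), bending modulus k_b = 2.7e-19 J, zero
spontaneous curvature, interior (hemoglobin) viscosity 0.005 Pa s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

UM = 1e-6  # µm -> m

G_S_DEFAULT = 2.5e-6      # N/m
C_DIL_DEFAULT = 100.0     # dimensionless
K_B_DEFAULT = 2.7e-19     # J
VISC_INTERIOR_DEFAULT = 0.005  # Pa s
RBC_END_TO_END = 7.8      # µm
RBC_AREA = 134.1          # µm²
RBC_VOLUME = 94.1         # µm³


def _check_closed_oriented(triangles: np.ndarray) -> None:
    directed = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]],
                               triangles[:, [2, 0]]])
    uniq = np.unique(directed, axis=0)
    if len(uniq) != len(directed):
        raise ValueError("inconsistent triangle orientation: a directed edge "
                         "appears twice")
    und = np.unique(np.sort(directed, axis=1), axis=0)
    if len(directed) != 2 * len(und):
        raise ValueError("surface is not closed")


def area_volume(vertices: np.ndarray, triangles: np.ndarray) -> tuple[float, float]:
    """Total surface area (µm²) and enclosed volume (µm³) of a closed mesh.

    The volume is the sum of signed tetrahedra about the centroid, which is
    exactly translation invariant; consistent outward orientation is required
    and checked.
    """
    triangles = np.asarray(triangles)
    _check_closed_oriented(triangles)
    p = np.asarray(vertices, float) - np.mean(vertices, axis=0)
    tri = p[triangles]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area = 0.5 * np.linalg.norm(cross, axis=1).sum()
    vol = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    if vol < 0:
        raise ValueError("triangles are oriented inward; expected outward "
                         "orientation")
    return float(area), float(vol)


@dataclass
class ForceDensity:
    """Lumped nodal membrane forces in newtons."""

    elastic: np.ndarray
    bending: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.elastic + self.bending

    def check_balance(self, vertices_um: np.ndarray,
                      rtol_force: float = 1e-12, rtol_torque: float = 1e-10) -> None:
        """Assert zero net force and zero net torque about the centroid."""
        f = self.total
        scale = np.abs(f).sum() + 1e-300
        if np.linalg.norm(f.sum(axis=0)) > rtol_force * scale:
            raise ValueError("net membrane force is nonzero")
        r = (vertices_um - vertices_um.mean(axis=0)) * UM
        torque = np.cross(r, f).sum(axis=0)
        tscale = (np.linalg.norm(r, axis=1) * np.linalg.norm(f, axis=1)).sum() + 1e-300
        if np.linalg.norm(torque) > rtol_torque * tscale:
            raise ValueError("net membrane torque is nonzero")


@dataclass
class CellMembrane:
    """Closed triangulated RBC membrane with reference (resting) metrics."""

    vertices: np.ndarray          # reference positions, µm
    triangles: np.ndarray
    G_s: float = G_S_DEFAULT      # N/m
    C_dil: float = C_DIL_DEFAULT
    k_b: float = K_B_DEFAULT      # J
    c0: float = 0.0               # spontaneous curvature, 1/µm
    viscosity_interior: float = VISC_INTERIOR_DEFAULT  # Pa s

    # derived reference quantities (filled in __post_init__)
    ref_inv: np.ndarray = field(init=False, repr=False)    # (m, 2, 2), 1/m
    ref_area: np.ndarray = field(init=False, repr=False)   # (m,), m²
    bend_L: sparse.csr_matrix = field(init=False, repr=False)
    bend_A: np.ndarray = field(init=False, repr=False)     # (n,), m²
    reference_area: float = field(init=False)              # µm²
    reference_volume: float = field(init=False)            # µm³

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.triangles = np.asarray(self.triangles, np.int64)
        _check_closed_oriented(self.triangles)
        self.reference_area, self.reference_volume = area_volume(
            self.vertices, self.triangles)
        self._build_reference_metrics()
        self._build_bending_operator()

    # -- reference metrics for the in-plane (Skalak) law -------------------
    def _build_reference_metrics(self) -> None:
        x = self.vertices * UM
        tri = x[self.triangles]
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]
        l1 = np.linalg.norm(e1, axis=1)
        p = np.einsum("ij,ij->i", e1, e2) / l1
        q = np.linalg.norm(np.cross(e1, e2), axis=1) / l1
        if np.any(q <= 0):
            raise ValueError("degenerate reference triangle")
        # reference edge matrix R = [[l1, p], [0, q]]; store its inverse
        inv = np.zeros((len(tri), 2, 2))
        inv[:, 0, 0] = 1.0 / l1
        inv[:, 0, 1] = -p / (l1 * q)
        inv[:, 1, 1] = 1.0 / q
        self.ref_inv = inv
        self.ref_area = 0.5 * l1 * q

    # -- frozen-reference cotangent operator for bending -------------------
    def _build_bending_operator(self) -> None:
        x = self.vertices * UM
        n = len(x)
        tri = self.triangles
        rows, cols, vals = [], [], []
        for k in range(3):
            i = tri[:, k]
            j = tri[:, (k + 1) % 3]
            o = tri[:, (k + 2) % 3]
            u = x[i] - x[o]
            v = x[j] - x[o]
            cot = np.einsum("ij,ij->i", u, v) / np.linalg.norm(
                np.cross(u, v), axis=1)
            w = 0.5 * cot
            rows += [i, j, i, j]
            cols += [j, i, i, j]
            vals += [w, w, -w, -w]
        L = sparse.coo_matrix((np.concatenate(vals),
                               (np.concatenate(rows), np.concatenate(cols))),
                              shape=(n, n)).tocsr()
        self.bend_L = L
        areas = 0.5 * np.linalg.norm(
            np.cross(x[tri[:, 1]] - x[tri[:, 0]], x[tri[:, 2]] - x[tri[:, 0]]),
            axis=1)
        va = np.zeros(n)
        np.add.at(va, tri.ravel(), np.repeat(areas / 3.0, 3))
        self.bend_A = va

    # -- convenience -------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def area_volume(self, current_vertices: np.ndarray | None = None) -> tuple[float, float]:
        v = self.vertices if current_vertices is None else current_vertices
        return area_volume(v, self.triangles)

    def bounding_radius(self) -> float:
        c = self.vertices.mean(axis=0)
        return float(np.linalg.norm(self.vertices - c, axis=1).max())


def make_biconcave(end_to_end: float = RBC_END_TO_END, n_refine: int = 4,
                   sphere_path: bool = False, **moduli) -> CellMembrane:
    """Construct the biconcave resting cell (reference metrics stored).

    ``n_refine`` is the icosphere subdivision level (>= 2).  The canonical
    cell (7.8 µm end-to-end) has surface area 134.1 µm² and volume 94.1 µm³.
    """
    if n_refine < 2:
        raise ValueError("n_refine must be >= 2")
    from .shapes import biconcave_vertices

    verts, faces = biconcave_vertices(end_to_end, n_refine,
                                      sphere_path=sphere_path)
    # consistent outward orientation
    c = verts.mean(axis=0)
    tri = verts[faces]
    out = np.einsum("ij,ij->i",
                    np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]),
                    tri.mean(axis=1) - c)
    if np.median(out) < 0:
        faces = faces[:, [0, 2, 1]]
    return CellMembrane(verts, faces, **moduli)
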