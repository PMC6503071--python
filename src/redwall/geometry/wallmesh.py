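"""Triangulated vessel-wall surfaces.

A :class:`WallMesh` is the Lagrangian representation of the vessel wall: an
open-ended (capped-at-inlets/outlets) triangulated surface with outward unit
normals, a per-vertex region-of-interest (ROI) label, and a per-vertex area
weight ``dA`` used for area-weighted surface averages.

Coordinates are in micrometres throughout the geometry layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

CAP_LABEL = "cap"


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Areas of all triangles, in µm²."""
    p = vertices[triangles]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return 0.5 * np.linalg.norm(n, axis=1)


def vertex_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Barycentric vertex area weights: one third of each incident triangle.

    Their sum equals the total mesh area exactly (up to roundoff), which is
    the property the surface-average quadrature relies on.
    """
    areas = triangle_areas(vertices, triangles)
    va = np.zeros(len(vertices))
    np.add.at(va, triangles.ravel(), np.repeat(areas / 3.0, 3))
    return va


def edge_counts(triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique undirected edges and the number of triangles sharing each."""
    e = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]],
                        triangles[:, [2, 0]]])
    e = np.sort(e, axis=1)
    edges, counts = np.unique(e, axis=0, return_counts=True)
    return edges, counts


def boundary_loops(triangles: np.ndarray) -> list[np.ndarray]:
    """Ordered vertex loops of the open boundary (caps)."""
    # Directed boundary edges appear exactly once.
    directed = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]],
                               triangles[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True,
                               return_counts=True)
    bdry = directed[counts[inv] == 1]
    nxt = dict(zip(bdry[:, 0].tolist(), bdry[:, 1].tolist()))
    loops = []
    visited: set[int] = set()
    for start in nxt:
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur = nxt.get(start)
        while cur is not None and cur != start and cur not in visited:
            loop.append(cur)
            visited.add(cur)
            cur = nxt.get(cur)
        loops.append(np.asarray(loop))
    return loops


@dataclass
class WallMesh:
    """Triangulated vessel wall with ROI labels and vertex quadrature weights.

    Parameters
    ----------
    vertices : (n, 3) float array, µm.
    triangles : (m, 3) int array, counter-clockwise seen from outside.
    normals : (n, 3) outward unit normals.
    roi_labels : (n,) array of str, e.g. ``"vessel:0"``, ``"bifurcation:0"``,
        ``"convergence:0"`` or ``"cap"`` for vertices on an open boundary ring.
    distance_fn : optional analytic signed-distance callable (negative inside
        the lumen), attached by the generators so the flow solver and the
        sampled distance field agree exactly with the construction geometry.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    normals: np.ndarray
    roi_labels: np.ndarray
    vertex_area: np.ndarray = field(default=None)  # type: ignore[assignment]
    distance_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.normals = np.asarray(self.normals, dtype=float)
        self.roi_labels = np.asarray(self.roi_labels, dtype=object)
        if self.vertex_area is None:
            self.vertex_area = vertex_areas(self.vertices, self.triangles)

    # -- geometry ---------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_areas(self) -> np.ndarray:
        return triangle_areas(self.vertices, self.triangles)

    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    # -- topology ---------------------------------------------------------
    def is_watertight_except_caps(self) -> bool:
        """Every edge is shared by exactly 2 triangles, or 1 on a cap ring."""
        _, counts = edge_counts(self.triangles)
        return bool(np.all((counts == 2) | (counts == 1)))

    def boundary_loops(self) -> list[np.ndarray]:
        return boundary_loops(self.triangles)

    def euler_characteristic_capped(self) -> int:
        """Euler characteristic after capping each boundary loop with a disk.

        For a genus-0 vessel surface this equals 2.
        """
        edges, _ = edge_counts(self.triangles)
        used = np.unique(self.triangles)
        chi_open = len(used) - len(edges) + len(self.triangles)
        return chi_open + len(self.boundary_loops())

    # -- labels ------------------------------------------------------------
    def roi_vertices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.roi_labels == label)

    def roi_names(self, include_caps: bool = False) -> list[str]:
        names = sorted({str(l) for l in self.roi_labels})
        if not include_caps and CAP_LABEL in names:
            names.remove(CAP_LABEL)
        return names

    def validate(self) -> None:
        """Raise ``ValueError`` on violated surface invariants."""
        if np.any(self.triangle_areas() <= 0):
            raise ValueError("degenerate triangle with non-positive area")
        norm = np.linalg.norm(self.normals, axis=1)
        if np.max(np.abs(norm - 1.0)) > 1e-10:
            raise ValueError("normals are not unit length")
        if not self.is_watertight_except_caps():
            raise ValueError("surface is not watertight away from caps")
        rel = abs(self.vertex_area.sum() - self.total_area()) / self.total_area()
        if rel > 1e-8:
            raise ValueError("vertex areas do not sum to the mesh area")

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.triangles.copy(),
                               process=False)
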