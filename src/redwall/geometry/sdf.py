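"""Signed-distance fields of vessel lumens.

The flow solver classifies its Cartesian grid against a signed distance to
the vessel wall (negative inside the lumen).  Generators attach an analytic
distance callable to their meshes (axis formula for straight tubes, capsule
unions over centerline polylines otherwise); meshes without one fall back to
a nearest-triangle query with a ray-cast sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .wallmesh import WallMesh


@dataclass
class DistanceField:
    """Signed distance sampled on a uniform node grid, plus the exact callable.

    ``values[i, j, k]`` is the signed distance (µm, negative inside the lumen)
    at ``origin + h * (i, j, k)``.  ``fn`` is the analytic callable when the
    geometry provides one; sampling prefers it.
    """

    origin: np.ndarray
    h: float
    values: np.ndarray
    fn: Callable[[np.ndarray], np.ndarray] | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def sample(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        if self.fn is not None:
            return self.fn(points)
        return self._trilinear(points)

    def _trilinear(self, points: np.ndarray) -> np.ndarray:
        g = (points - self.origin) / self.h
        nx, ny, nz = self.values.shape
        i0 = np.clip(np.floor(g).astype(int), 0, [nx - 2, ny - 2, nz - 2])
        f = np.clip(g - i0, 0.0, 1.0)
        out = np.zeros(len(points))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (np.where(dx, f[:, 0], 1 - f[:, 0])
                         * np.where(dy, f[:, 1], 1 - f[:, 1])
                         * np.where(dz, f[:, 2], 1 - f[:, 2]))
                    out += w * self.values[i0[:, 0] + dx, i0[:, 1] + dy,
                                           i0[:, 2] + dz]
        return out

    def gradient(self, points: np.ndarray, eps: float | None = None) -> np.ndarray:
        """Unit-magnitude (away from the medial axis) distance gradient."""
        points = np.atleast_2d(points)
        eps = eps if eps is not None else 0.25 * self.h
        g = np.empty_like(points)
        for ax in range(3):
            dp = np.zeros(3)
            dp[ax] = eps
            g[:, ax] = (self.sample(points + dp) - self.sample(points - dp)) / (2 * eps)
        return g

    def nearest_wall_point(self, points: np.ndarray) -> np.ndarray:
        """First-order closest-point map ``x - phi(x) grad phi(x)``."""
        points = np.atleast_2d(points)
        phi = self.sample(points)
        grad = self.gradient(points)
        n = np.linalg.norm(grad, axis=1, keepdims=True)
        grad = grad / np.where(n == 0, 1.0, n)
        return points - phi[:, None] * grad


# -- analytic distance builders -------------------------------------------

def straight_tube_distance(radius: float, axis_point=(0.0, 0.0, 0.0),
                           axis=(1.0, 0.0, 0.0)) -> Callable[[np.ndarray], np.ndarray]:
    """Signed distance to an infinite circular cylinder wall (exact)."""
    p0 = np.asarray(axis_point, float)
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)

    def fn(points: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(points) - p0
        q = q - np.outer(q @ a, a)
        return np.linalg.norm(q, axis=1) - radius

    return fn


def capsule_union_distance(polylines: list[np.ndarray], radii: list[float],
                           chunk: int = 65536) -> Callable[[np.ndarray], np.ndarray]:
    """Signed distance to the union of round tubes swept along polylines.

    Exact for a single straight segment; the union takes a pointwise minimum
    (sharp blend at junctions).
    """
    segs_a, segs_b, segs_r = [], [], []
    for pts, r in zip(polylines, radii):
        pts = np.asarray(pts, float)
        segs_a.append(pts[:-1])
        segs_b.append(pts[1:])
        segs_r.append(np.full(len(pts) - 1, r))
    a = np.concatenate(segs_a)
    b = np.concatenate(segs_b)
    r = np.concatenate(segs_r)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0.0, 1.0, denom)

    def fn(points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        out = np.empty(len(points))
        for s in range(0, len(points), chunk):
            q = points[s:s + chunk, None, :] - a[None, :, :]
            t = np.clip(np.einsum("qij,ij->qi", q, ab) / denom, 0.0, 1.0)
            d = np.linalg.norm(q - t[..., None] * ab[None], axis=2) - r[None, :]
            out[s:s + chunk] = d.min(axis=1)
        return out

    return fn


def sample_distance_grid(fn: Callable[[np.ndarray], np.ndarray],
                         origin: np.ndarray, h: float,
                         shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = shape
    xs = origin[0] + h * np.arange(nx)
    ys = origin[1] + h * np.arange(ny)
    zs = origin[2] + h * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return fn(pts).reshape(shape)


def signed_distance(mesh: WallMesh, h: float, margin: float = 2.0,
                    min_diameter: float | None = None) -> DistanceField:
    """Sample the signed distance to a wall mesh on a uniform node grid.

    Uses the analytic callable attached by the generator when present;
    otherwise falls back to a nearest-triangle query with the sign taken
    from containment in the cap-closed surface.
    """
    if min_diameter is not None and h > min_diameter / 8.0 + 1e-12:
        raise ValueError(
            f"grid spacing h={h} µm too coarse: must satisfy "
            f"h <= min diameter / 8 = {min_diameter / 8.0:.3f} µm")
    if not mesh.is_watertight_except_caps():
        raise ValueError("lateral surface is not watertight; refusing to "
                         "build a signed-distance field")
    lo = mesh.vertices.min(axis=0) - margin
    hi = mesh.vertices.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[ax] - lo[ax]) / h)) + 1 for ax in range(3))
    fn = mesh.distance_fn
    if fn is None:
        fn = mesh_distance_function(mesh)
    values = sample_distance_grid(fn, lo, h, shape)  # type: ignore[arg-type]
    return DistanceField(origin=lo, h=h, values=values, fn=fn)


def mesh_distance_function(mesh: WallMesh, k: int = 16):
    """Signed distance from nearest-triangle queries on the mesh itself."""
    import trimesh

    tm = mesh.as_trimesh()
    # close the caps with triangle fans so containment is well defined
    closed_faces = [tm.faces]
    verts = [tm.vertices]
    nv = len(tm.vertices)
    for loop in mesh.boundary_loops():
        centroid = mesh.vertices[loop].mean(axis=0)
        verts.append(centroid[None])
        idx = np.arange(len(loop))
        fan = np.column_stack([loop[idx], loop[np.roll(idx, -1)],
                               np.full(len(loop), nv)])
        closed_faces.append(fan)
        nv += 1
    closed = trimesh.Trimesh(np.vstack(verts), np.vstack(closed_faces),
                             process=False)
    tri_pts = mesh.vertices[mesh.triangles]
    centroids = tri_pts.mean(axis=1)
    tree = cKDTree(centroids)

    def fn(points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        _, cand = tree.query(points, k=min(k, len(centroids)))
        cand = np.atleast_2d(cand)
        best = np.full(len(points), np.inf)
        for j in range(cand.shape[1]):
            tri = tri_pts[cand[:, j]]
            closest = trimesh.triangles.closest_point(tri, points)
            d = np.linalg.norm(points - closest, axis=1)
            best = np.minimum(best, d)
        inside = closed.contains(points)
        return np.where(inside, -best, best)

    return fn
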