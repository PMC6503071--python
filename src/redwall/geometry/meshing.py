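"""Implicit-surface meshing shared by the junction and network generators.

Junction and network lumens are defined as unions of round capsules along
centerline polylines; the wall surface is the zero level set extracted by
marching cubes, with open inlet/outlet caps produced by plane slicing.
Vertex normals come from the signed-distance gradient, so they are exact for
the capsule-union geometry rather than mesh-averaged.
"""

from __future__ import annotations

import numpy as np

from .sdf import sample_distance_grid
from .wallmesh import CAP_LABEL, WallMesh


def mesh_implicit(dist_fn, lo: np.ndarray, hi: np.ndarray, mc_h: float,
                  cap_planes: list[tuple[np.ndarray, np.ndarray]],
                  label_fn) -> WallMesh:
    """Extract the zero level set of ``dist_fn`` and open the caps.

    ``cap_planes`` is a list of ``(origin, inward_normal)``: geometry on the
    anti-normal side of each plane is cut away, leaving an open boundary ring.
    ``label_fn(points) -> array of str`` assigns ROI labels; cut-ring vertices
    are relabeled ``"cap"``.
    """
    import trimesh
    from skimage import measure

    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    shape = tuple(int(np.ceil((hi[ax] - lo[ax]) / mc_h)) + 1 for ax in range(3))
    vol = sample_distance_grid(dist_fn, lo, mc_h, shape)
    if vol.min() > 0:
        raise ValueError("empty lumen: the implicit surface has no interior "
                         "inside the meshing box")
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0,
                                                spacing=(mc_h, mc_h, mc_h))
    verts = verts + lo
    tm = trimesh.Trimesh(verts, faces, process=True, validate=True)
    if not tm.is_watertight:
        raise ValueError("marching-cubes surface is not closed; enlarge the "
                         "meshing box or refine mc_h")
    for origin, normal in cap_planes:
        tm = trimesh.intersections.slice_mesh_plane(
            tm, plane_normal=np.asarray(normal, float),
            plane_origin=np.asarray(origin, float), cap=False)
    tm.merge_vertices()
    tm.remove_unreferenced_vertices()

    verts = np.asarray(tm.vertices)
    faces = np.asarray(tm.faces)

    grad = _fd_gradient(dist_fn, verts, 0.25 * mc_h)
    normals = grad / np.linalg.norm(grad, axis=1, keepdims=True)

    # orient faces outward (consistent with the distance gradient)
    p = verts[faces]
    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    vn = normals[faces].mean(axis=1)
    if np.einsum("ij,ij->i", fn, vn).mean() < 0:
        faces = faces[:, [0, 2, 1]]

    labels = np.asarray(label_fn(verts), dtype=object)
    mesh = WallMesh(verts, faces, normals, labels, distance_fn=dist_fn)
    for loop in mesh.boundary_loops():
        mesh.roi_labels[loop] = CAP_LABEL
    return mesh


def _fd_gradient(fn, points: np.ndarray, eps: float) -> np.ndarray:
    g = np.empty_like(points)
    for ax in range(3):
        dp = np.zeros(3)
        dp[ax] = eps
        g[:, ax] = (fn(points + dp) - fn(points - dp)) / (2 * eps)
    return g
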