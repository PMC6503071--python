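"""WSS surface gradients by second-order central differencing.

The axial (circumferential) gradient at a vertex steps ±span/2 along the
local e_s (e_theta) tangent, projects the endpoints back onto the wall
surface (closest point on the triangulation), interpolates tau there with
the barycentric weights of the containing triangle — exact for fields
linear over the surface — and central-differences over the projected
spacing.  The stencil spans the same total distance as the traction
stencil.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ..geometry.wallmesh import WallMesh
from .fields import LocalFrame, WSSField, WSSGField


def closest_point_barycentric(mesh: WallMesh, points: np.ndarray, k: int = 8):
    """Closest surface point, its triangle, and barycentric weights."""
    import trimesh

    tri_pts = mesh.vertices[mesh.triangles]
    tree = cKDTree(tri_pts.mean(axis=1))
    _, cand = tree.query(points, k=min(k, len(tri_pts)))
    cand = np.atleast_2d(cand)
    best_d = np.full(len(points), np.inf)
    best_cp = points.copy()
    best_tri = np.zeros(len(points), dtype=np.int64)
    for j in range(cand.shape[1]):
        cp = trimesh.triangles.closest_point(tri_pts[cand[:, j]], points)
        d = np.linalg.norm(points - cp, axis=1)
        closer = d < best_d
        best_d[closer] = d[closer]
        best_cp[closer] = cp[closer]
        best_tri[closer] = cand[closer, j]
    bary = trimesh.triangles.points_to_barycentric(tri_pts[best_tri], best_cp)
    bary = np.clip(bary, 0.0, 1.0)
    bary /= bary.sum(axis=1, keepdims=True)
    return best_cp, best_tri, bary


def wssg(wss: WSSField, mesh: WallMesh, frames: LocalFrame,
         stencil_span: float = 0.3) -> WSSGField:
    """Axial and circumferential WSS gradients (dyne/cm²/µm) per vertex.

    Vertices whose stencil touches an invalid or cap vertex are flagged.
    """
    delta = stencil_span / 2.0
    tau = wss.t_s
    usable = wss.valid & (mesh.roi_labels != "cap")
    out = {}
    valid = wss.valid.copy()
    for name, tangent in (("s", frames.e_s), ("theta", frames.e_theta)):
        plus = mesh.vertices + delta * tangent
        minus = mesh.vertices - delta * tangent
        cp_p, tri_p, bar_p = closest_point_barycentric(mesh, plus)
        cp_m, tri_m, bar_m = closest_point_barycentric(mesh, minus)
        tau_p = (tau[mesh.triangles[tri_p]] * bar_p).sum(axis=1)
        tau_m = (tau[mesh.triangles[tri_m]] * bar_m).sum(axis=1)
        spacing = np.linalg.norm(cp_p - cp_m, axis=1)
        degenerate = spacing < 1e-9
        spacing[degenerate] = 1.0
        out[name] = (tau_p - tau_m) / spacing
        touched = usable[mesh.triangles[tri_p]].all(axis=1) \
            & usable[mesh.triangles[tri_m]].all(axis=1)
        valid &= touched & ~degenerate
    return WSSGField(grad_s=out["s"], grad_theta=out["theta"], valid=valid)
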