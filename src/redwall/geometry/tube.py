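"""Straight and curved tube fixtures, swept as structured ring meshes."""

from __future__ import annotations

import numpy as np

from .centerline import parallel_transport_frames
from .network import NetworkSpec, Vessel
from .sdf import capsule_union_distance, straight_tube_distance
from .wallmesh import CAP_LABEL, WallMesh


def make_tube(diameter: float, length: float, curvature_profile=None,
              mesh_size: float = 0.5) -> tuple[WallMesh, NetworkSpec]:
    """Generate an open-ended circular tube along x.

    Parameters
    ----------
    diameter, length : µm.  Diameter must lie in [4, 30] µm.
    curvature_profile : ``None`` for a straight tube, or a callable
        ``profile(x, length) -> (n, 2)`` transverse (y, z) centerline offset
        in µm (see :func:`redwall.geometry.centerline.sinusoidal_bend`).
    mesh_size : target triangle edge length, µm; must be < diameter / 6.

    Returns the wall mesh (vertices exactly at radius ``diameter/2`` from the
    centerline) and a single-vessel :class:`NetworkSpec`.
    """
    if not (4.0 <= diameter <= 30.0):
        raise ValueError(f"diameter {diameter} µm outside the supported "
                         "range [4, 30] µm")
    if mesh_size >= diameter / 6.0:
        raise ValueError(
            f"mesh_size {mesh_size} µm too coarse: the tube surface requires "
            f"mesh_size < diameter/6 = {diameter / 6.0:.3f} µm")

    R = 0.5 * diameter
    n_ax = max(2, int(round(length / mesh_size)) + 1)
    xs = np.linspace(0.0, length, n_ax)
    if curvature_profile is None:
        centerline = np.column_stack([xs, np.zeros(n_ax), np.zeros(n_ax)])
        t_hat = np.tile([1.0, 0.0, 0.0], (n_ax, 1))
        e1 = np.tile([0.0, 1.0, 0.0], (n_ax, 1))
        e2 = np.tile([0.0, 0.0, 1.0], (n_ax, 1))
    else:
        off = np.asarray(curvature_profile(xs, length), float)
        centerline = np.column_stack([xs, off[:, 0], off[:, 1]])
        t_hat, e1, e2 = parallel_transport_frames(centerline)

    n_circ = max(8, int(round(np.pi * diameter / mesh_size)))
    theta = 2.0 * np.pi * np.arange(n_circ) / n_circ
    ct, st = np.cos(theta), np.sin(theta)

    verts = (centerline[:, None, :]
             + R * (ct[None, :, None] * e1[:, None, :]
                    + st[None, :, None] * e2[:, None, :]))
    normals = (ct[None, :, None] * e1[:, None, :]
               + st[None, :, None] * e2[:, None, :])
    verts = verts.reshape(-1, 3)
    normals = normals.reshape(-1, 3)

    tris = []
    for i in range(n_ax - 1):
        j = np.arange(n_circ)
        jp = (j + 1) % n_circ
        a = i * n_circ + j
        b = i * n_circ + jp
        c = (i + 1) * n_circ + j
        d = (i + 1) * n_circ + jp
        tris.append(np.column_stack([a, c, b]))
        tris.append(np.column_stack([b, c, d]))
    triangles = np.vstack(tris)

    # orient outward: flip winding if face normals oppose the radial normals
    p = verts[triangles]
    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    vn = normals[triangles].mean(axis=1)
    if np.einsum("ij,ij->i", fn, vn).mean() < 0:
        triangles = triangles[:, [0, 2, 1]]

    labels = np.array(["vessel:0"] * len(verts), dtype=object)
    labels[:n_circ] = CAP_LABEL
    labels[-n_circ:] = CAP_LABEL

    if curvature_profile is None:
        dist = straight_tube_distance(R)
    else:
        # fine polyline extended beyond both caps so the sampled lumen stays
        # open through the axial box faces (periodic fixtures rely on this)
        xf = np.linspace(-0.25 * length, 1.25 * length, 768)
        offf = np.asarray(curvature_profile(xf, length), float)
        poly = np.column_stack([xf, offf[:, 0], offf[:, 1]])
        dist = capsule_union_distance([poly], [R])

    mesh = WallMesh(verts, triangles, normals, labels, distance_fn=dist)
    spec = NetworkSpec([Vessel(0, centerline, diameter, 1, "capillary")],
                       junctions=[], inlets=[0], outlets=[0])
    return mesh, spec
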