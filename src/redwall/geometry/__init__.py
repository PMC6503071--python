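"""Synthetic microvessel geometry: tubes, junctions, networks, distance fields."""

from .centerline import (cumulative_arc_length, parallel_transport_frames,
                         polyline_arc_length, sinusoidal_bend)
from .junction import make_junction
from .network import (DIAMETER_BOUNDS, LENGTH_BOUNDS, Junction, NetworkSpec,
                      Vessel, build_network)
from .sdf import (DistanceField, capsule_union_distance, signed_distance,
                  straight_tube_distance)
from .tube import make_tube
from .wallmesh import CAP_LABEL, WallMesh, triangle_areas, vertex_areas

__all__ = [
    "CAP_LABEL", "DIAMETER_BOUNDS", "DistanceField", "Junction",
    "LENGTH_BOUNDS", "NetworkSpec", "Vessel", "WallMesh", "build_network",
    "capsule_union_distance", "cumulative_arc_length", "make_junction",
    "make_network", "make_tube", "mesh_network",
    "parallel_transport_frames", "polyline_arc_length", "signed_distance",
    "sinusoidal_bend", "straight_tube_distance", "triangle_areas",
    "vertex_areas",
]


def mesh_network(spec: NetworkSpec, mesh_size: float | None = None) -> WallMesh:
    """Triangulate the wall surface of a whole network specification."""
    import numpy as np

    from .meshing import mesh_implicit

    mesh_size = (mesh_size if mesh_size is not None
                 else min(v.diameter for v in spec.vessels) / 9.0)
    polys, radii = [], []
    cap_planes = []
    for v in spec.vessels:
        pts = v.centerline.copy()
        if v.id in spec.inlets:
            t = pts[0] - pts[1]
            t = t / np.linalg.norm(t)
            cap_planes.append((pts[0].copy(), -t))
            pts = np.vstack([pts[0] + 3.0 * v.radius * t, pts])
        if v.id in spec.outlets:
            t = pts[-1] - pts[-2]
            t = t / np.linalg.norm(t)
            cap_planes.append((pts[-1].copy(), -t))
            pts = np.vstack([pts, pts[-1] + 3.0 * v.radius * t])
        polys.append(pts)
        radii.append(v.radius)
    dist = capsule_union_distance(polys, radii)
    allpts = np.vstack(polys)
    rmax = max(radii)
    lo = allpts.min(axis=0) - (rmax + 3 * mesh_size)
    hi = allpts.max(axis=0) + (rmax + 3 * mesh_size)

    from .centerline import segment_distance

    def label_fn(verts: np.ndarray) -> np.ndarray:
        labels = np.empty(len(verts), dtype=object)
        dmin = np.full(len(verts), np.inf)
        for v in spec.vessels:
            d = np.abs(segment_distance(v.centerline, verts) - v.radius)
            better = d < dmin
            dmin[better] = d[better]
            labels[better] = f"vessel:{v.id}"
        for j in spec.junctions:
            feeder_d = max(spec.vessel(f).diameter for f in j.feeders)
            near = np.linalg.norm(verts - j.center, axis=1) <= feeder_d
            labels[near] = f"{j.kind}:{j.id}"
        return labels

    return mesh_implicit(dist, lo, hi, mesh_size, cap_planes, label_fn)


def make_network(n_orders: int = 3, horton_ratio: float = 1.6,
                 tortuosity: float = 0.3, seed: int = 0,
                 mesh_size: float | None = None,
                 **kwargs) -> tuple[WallMesh, NetworkSpec]:
    """Build a network specification and its triangulated wall surface."""
    spec = build_network(n_orders, horton_ratio, tortuosity, seed, **kwargs)
    return mesh_network(spec, mesh_size), spec
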