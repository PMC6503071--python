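"""Single bifurcation / convergence fixtures."""

from __future__ import annotations

import numpy as np

from .meshing import mesh_implicit
from .network import Junction, NetworkSpec, Vessel
from .sdf import capsule_union_distance
from .wallmesh import WallMesh

#: a junction region extends this many feeder diameters from the junction
#: center along each branch (configurable; the visual extent of bifurcation
#: regions in intravital maps motivates one diameter)
JUNCTION_EXTENT_DIAMETERS = 1.0


def make_junction(kind: str, feeder_diameter: float,
                  branch_diameters: tuple[float, float],
                  angles: tuple[float, float],
                  mesh_size: float | None = None,
                  branch_length: float | None = None,
                  allow_larger_branches: bool = False,
                  junction_extent: float | None = None
                  ) -> tuple[WallMesh, NetworkSpec]:
    """Generate a single junction: one feeder and two branches (bifurcation)
    or two feeders and one collector (convergence).

    ``angles`` are the two branch (feeder, for a convergence) angles off the
    main axis, in degrees.  The surface is watertight with three open caps.
    """
    if kind not in ("bifurcation", "convergence"):
        raise ValueError("kind must be 'bifurcation' or 'convergence'")
    d1, d2 = branch_diameters
    if kind == "bifurcation" and not allow_larger_branches and \
            max(d1, d2) > feeder_diameter + 1e-12:
        raise ValueError("daughter branches wider than the feeder; pass "
                         "allow_larger_branches=True to override")
    a1, a2 = np.deg2rad(angles[0]), np.deg2rad(angles[1])
    if abs(angles[0]) + abs(angles[1]) < 20.0:
        raise ValueError("branch angles too shallow: the two branch lumens "
                         "would overlap along their length (self-intersecting "
                         "surface)")
    if max(abs(angles[0]), abs(angles[1])) > 80.0:
        raise ValueError("branch angle too steep: branch lumen folds back "
                         "onto the feeder (self-intersecting surface)")

    mesh_size = mesh_size if mesh_size is not None else min(feeder_diameter,
                                                            d1, d2) / 10.0
    L0 = branch_length if branch_length is not None else 2.5 * feeder_diameter

    # main vessel along x toward origin; branches leave at +-angles in xy
    dir1 = np.array([np.cos(a1), np.sin(a1), 0.0])
    dir2 = np.array([np.cos(a2), -np.sin(a2), 0.0])
    p_main = np.array([-L0, 0.0, 0.0])
    zero = np.zeros(3)
    polys = [np.vstack([p_main, zero]),
             np.vstack([zero, L0 * dir1]),
             np.vstack([zero, L0 * dir2])]
    radii = [feeder_diameter / 2.0, d1 / 2.0, d2 / 2.0]

    # extend each capsule beyond its cap plane so marching cubes closes the
    # surface outside the box that matters, then slice the caps open
    ext = 3.0 * max(radii)
    polys_ext = [np.vstack([p_main - np.array([ext, 0, 0]), zero]),
                 np.vstack([zero, (L0 + ext) * dir1]),
                 np.vstack([zero, (L0 + ext) * dir2])]
    dist = capsule_union_distance(polys_ext, radii)

    pts = np.vstack(polys_ext)
    lo = pts.min(axis=0) - (max(radii) + 3 * mesh_size)
    hi = pts.max(axis=0) + (max(radii) + 3 * mesh_size)

    cap_planes = [(p_main, np.array([1.0, 0.0, 0.0])),
                  (L0 * dir1, -dir1),
                  (L0 * dir2, -dir2)]

    extent = (junction_extent if junction_extent is not None
              else JUNCTION_EXTENT_DIAMETERS * feeder_diameter)
    seg_dirs = [np.array([1.0, 0.0, 0.0]), dir1, dir2]
    seg_starts = [p_main, zero, zero]
    # spec vessel id owning each capsule segment (main, branch1, branch2)
    seg_ids = [0, 1, 2] if kind == "bifurcation" else [2, 0, 1]

    def label_fn(verts: np.ndarray) -> np.ndarray:
        labels = np.empty(len(verts), dtype=object)
        r = np.linalg.norm(verts, axis=1)
        # nearest branch axis decides the vessel label
        dmin = np.full(len(verts), np.inf)
        owner = np.zeros(len(verts), dtype=int)
        for i, (s, d, rad) in enumerate(zip(seg_starts, seg_dirs, radii)):
            q = verts - s
            t = np.clip(q @ d, 0.0, L0 + ext)
            dist_ax = np.linalg.norm(q - t[:, None] * d[None], axis=1) - rad
            better = np.abs(dist_ax) < dmin
            dmin[better] = np.abs(dist_ax)[better]
            owner[better] = seg_ids[i]
        labels[:] = [f"vessel:{o}" for o in owner]
        labels[r <= extent] = f"{kind}:0"
        return labels

    mesh = mesh_implicit(dist, lo, hi, mesh_size, cap_planes, label_fn)

    n_ax = 9
    if kind == "bifurcation":
        vessels = [
            Vessel(0, np.linspace(p_main, zero, n_ax), feeder_diameter, 2, "arteriole"),
            Vessel(1, np.linspace(zero, L0 * dir1, n_ax), d1, 1, "capillary"),
            Vessel(2, np.linspace(zero, L0 * dir2, n_ax), d2, 1, "capillary"),
        ]
        junctions = [Junction(0, "bifurcation", [0], [1, 2], zero)]
        inlets, outlets = [0], [1, 2]
    else:
        # two feeders flow toward the origin; the collector drains along -x
        vessels = [
            Vessel(0, np.linspace(L0 * dir1, zero, n_ax), d1, 1, "capillary"),
            Vessel(1, np.linspace(L0 * dir2, zero, n_ax), d2, 1, "capillary"),
            Vessel(2, np.linspace(zero, p_main, n_ax), feeder_diameter, 2, "venule"),
        ]
        junctions = [Junction(0, "convergence", [0, 1], [2], zero)]
        inlets, outlets = [0, 1], [2]
    spec = NetworkSpec(vessels, junctions, inlets, outlets)
    return mesh, spec
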