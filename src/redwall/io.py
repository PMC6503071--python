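"""File formats: VTP surfaces, STL, HDF5 field checkpoints, CSV tables.

VTP is plain XML; the writer emits ASCII PolyData readable by ParaView.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry.wallmesh import WallMesh


def write_vtp(path, vertices: np.ndarray, triangles: np.ndarray,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a triangulated surface with per-vertex arrays as ASCII VTP."""
    vertices = np.asarray(vertices, float)
    triangles = np.asarray(triangles)
    point_data = point_data or {}
    lines = []
    a = lines.append
    a('<?xml version="1.0"?>')
    a('<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">')
    a("  <PolyData>")
    a(f'    <Piece NumberOfPoints="{len(vertices)}" NumberOfVerts="0" '
      f'NumberOfLines="0" NumberOfStrips="0" NumberOfPolys="{len(triangles)}">')
    if point_data:
        a("      <PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            a(f'        <DataArray type="Float64" Name="{name}" '
              f'NumberOfComponents="{ncomp}" format="ascii">')
            a("          " + " ".join(f"{v:.10g}" for v in arr.ravel()))
            a("        </DataArray>")
        a("      </PointData>")
    a("      <Points>")
    a('        <DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    a("          " + " ".join(f"{v:.10g}" for v in vertices.ravel()))
    a("        </DataArray>")
    a("      </Points>")
    a("      <Polys>")
    a('        <DataArray type="Int64" Name="connectivity" format="ascii">')
    a("          " + " ".join(str(int(i)) for i in triangles.ravel()))
    a("        </DataArray>")
    a('        <DataArray type="Int64" Name="offsets" format="ascii">')
    a("          " + " ".join(str(3 * (i + 1)) for i in range(len(triangles))))
    a("        </DataArray>")
    a("      </Polys>")
    a("    </Piece>")
    a("  </PolyData>")
    a("</VTKFile>")
    Path(path).write_text("\n".join(lines))


def read_vtp_points(path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal reader: vertices and connectivity of a VTP written above."""
    from xml.etree import ElementTree as ET

    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    pts = piece.find("Points/DataArray")
    verts = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    conn = piece.find("Polys/DataArray[@Name='connectivity']")
    tris = np.fromstring(conn.text, sep=" ", dtype=np.int64).reshape(-1, 3)
    return verts, tris


def write_wall_vtp(path, mesh: WallMesh,
                   point_data: dict[str, np.ndarray] | None = None) -> None:
    data = dict(point_data or {})
    data.setdefault("normal", mesh.normals)
    data.setdefault("vertex_area", mesh.vertex_area)
    write_vtp(path, mesh.vertices, mesh.triangles, data)


def write_stl(path, mesh: WallMesh) -> None:
    mesh.as_trimesh().export(str(path))


def save_checkpoint(path, result, extra_meta: dict | None = None) -> None:
    """HDF5 checkpoint of a run: fields, cell states, monitors, config."""
    import h5py

    from .solver.simulation import RunResult

    assert isinstance(result, RunResult)
    with h5py.File(path, "w") as f:
        g = f.create_group("state")
        for c, name in enumerate("uvw"):
            g.create_dataset(name, data=result.state.u[c])
            g.create_dataset("mean_" + name, data=result.mean_u[c])
        g.create_dataset("p", data=result.state.p)
        g.create_dataset("mu", data=result.state.mu)
        g.create_dataset("mean_indicator", data=result.mean_indicator)
        g.attrs["t"] = result.state.t
        gg = f.create_group("grid")
        gg.attrs["origin"] = result.grid.origin
        gg.attrs["h"] = result.grid.h
        gg.attrs["shape"] = result.grid.shape
        gg.attrs["periodic_x"] = result.grid.periodic_x
        if result.ensemble is not None and result.ensemble.n_cells:
            f.create_dataset("cells/vertices", data=result.ensemble.vertices)
            f.create_dataset("cells/triangles",
                             data=result.ensemble.template.triangles)
            f["cells"].attrs["n_cells"] = result.ensemble.n_cells
        mg = f.create_group("monitors")
        for k, v in result.monitors.items():
            mg.create_dataset(k, data=np.asarray(v, dtype=float))
        meta = {"config": result.config.__dict__, "status": result.status}
        if extra_meta:
            meta.update(extra_meta)
        f.attrs["meta"] = json.dumps(meta)


def load_checkpoint_meta(path) -> dict:
    import h5py

    with h5py.File(path, "r") as f:
        return json.loads(f.attrs["meta"])


def write_monitors_csv(path, monitors: dict) -> None:
    import pandas as pd

    pd.DataFrame({k: v for k, v in monitors.items() if len(v)}).to_csv(
        path, index=False)
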