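"""Staggered Cartesian grid with sharp-interface wall classification.

The fluid occupies the lumen (signed distance < 0).  Velocity components
live on faces of a uniform MAC grid, pressure at cell centers.  Faces whose
center lies outside the lumen but near the wall are *ghost faces*: their
values are rebuilt every stage by mirror-image reflection of the no-slip
condition across the wall, which places the velocity zero at the wall to
second order and keeps one-sided near-wall velocity gradients accurate.

Geometry lives in µm; solver fields are SI (m, s, Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from ..geometry.sdf import DistanceField

UM = 1e-6

#: ghost faces are solid faces within this many h of the wall
GHOST_BAND = 2.0


def face_offsets(component: int) -> np.ndarray:
    """Offset (in units of h) of face (0,0,0) of a component from the box
    corner."""
    off = np.full(3, 0.5)
    off[component] = 0.0
    return off


@dataclass
class GhostSet:
    """Precomputed reflection data for the ghost faces of one component."""

    index: np.ndarray        # (g, 3) int face indices
    depth: np.ndarray        # (g,) distance behind the wall, µm (>= 0)
    # trilinear gathers for the two probe points inside the fluid
    stencil1: np.ndarray     # (g, 8, 3) int
    weights1: np.ndarray     # (g, 8)
    stencil2: np.ndarray
    weights2: np.ndarray
    b1: np.ndarray           # (g,) probe depths inside the fluid, µm
    b2: np.ndarray


@dataclass
class EulerianGrid:
    origin: np.ndarray            # µm, box corner
    h: float                      # µm, uniform
    shape: tuple[int, int, int]   # cell counts
    periodic_x: bool
    distance: DistanceField
    cell_fluid: np.ndarray = field(init=False)
    face_phi: list[np.ndarray] = field(init=False)
    face_fluid: list[np.ndarray] = field(init=False)
    ghosts: list[GhostSet] = field(init=False)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        phi_c = self.distance.sample(self.cell_centers().reshape(-1, 3))
        self.cell_fluid = (phi_c < 0).reshape(self.shape)
        if not self.cell_fluid.any():
            raise ValueError("no fluid cells: the lumen does not intersect "
                             "the grid box")
        if phi_c.min() > -2.0 * self.h:
            raise ValueError("lumen thinner than 4 grid cells everywhere; "
                             "unresolvable at this spacing")
        self.face_phi = []
        self.face_fluid = []
        self.ghosts = []
        for c in range(3):
            centers = self.face_centers(c)
            phi = self.distance.sample(centers.reshape(-1, 3)).reshape(
                centers.shape[:3])
            self.face_phi.append(phi)
            self.face_fluid.append(phi < 0)
            self.ghosts.append(self._build_ghosts(c, phi))

    # -- coordinates -------------------------------------------------------
    def face_shape(self, c: int) -> tuple[int, int, int]:
        s = list(self.shape)
        if c == 0:
            s[0] = s[0] if self.periodic_x else s[0] + 1
        else:
            s[c] += 1
        return tuple(s)  # type: ignore[return-value]

    def cell_centers(self) -> np.ndarray:
        cached = getattr(self, "_cell_centers", None)
        if cached is not None:
            return cached
        nx, ny, nz = self.shape
        xs = self.origin[0] + self.h * (np.arange(nx) + 0.5)
        ys = self.origin[1] + self.h * (np.arange(ny) + 0.5)
        zs = self.origin[2] + self.h * (np.arange(nz) + 0.5)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        self._cell_centers = np.stack([X, Y, Z], axis=-1)
        return self._cell_centers

    def face_centers(self, c: int) -> np.ndarray:
        off = face_offsets(c)
        s = self.face_shape(c)
        xs = self.origin[0] + self.h * (np.arange(s[0]) + off[0])
        ys = self.origin[1] + self.h * (np.arange(s[1]) + off[1])
        zs = self.origin[2] + self.h * (np.arange(s[2]) + off[2])
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)

    @property
    def box_length(self) -> np.ndarray:
        return self.h * np.asarray(self.shape, float)

    # -- ghost construction ------------------------------------------------
    def _trilinear_stencil(self, c: int, points: np.ndarray):
        """Gather indices/weights for trilinear interpolation on component c.

        Periodic wrap in x; clamped in y/z (callers keep points interior).
        """
        s = self.face_shape(c)
        off = face_offsets(c)
        g = (points - self.origin) / self.h - off
        i0 = np.floor(g).astype(int)
        f = g - i0
        idx = np.empty((len(points), 8, 3), dtype=np.int64)
        wts = np.empty((len(points), 8))
        k = 0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    ii = i0[:, 0] + dx
                    jj = np.clip(i0[:, 1] + dy, 0, s[1] - 1)
                    kk = np.clip(i0[:, 2] + dz, 0, s[2] - 1)
                    if c == 0 and self.periodic_x:
                        ii = ii % s[0]
                    else:
                        ii = np.clip(ii, 0, s[0] - 1)
                    idx[:, k, 0], idx[:, k, 1], idx[:, k, 2] = ii, jj, kk
                    wts[:, k] = (np.where(dx, f[:, 0], 1 - f[:, 0])
                                 * np.where(dy, f[:, 1], 1 - f[:, 1])
                                 * np.where(dz, f[:, 2], 1 - f[:, 2]))
                    k += 1
        return idx, wts

    def _build_ghosts(self, c: int, phi: np.ndarray) -> GhostSet:
        sel = (phi >= 0) & (phi < GHOST_BAND * self.h)
        index = np.argwhere(sel)
        if len(index) == 0:
            return GhostSet(index.reshape(0, 3), np.zeros(0),
                            np.zeros((0, 8, 3), np.int64), np.zeros((0, 8)),
                            np.zeros((0, 8, 3), np.int64), np.zeros((0, 8)),
                            np.zeros(0), np.zeros(0))
        off = face_offsets(c)
        pos = self.origin + self.h * (index + off)
        depth = phi[sel.nonzero()]
        nrm = self.distance.gradient(pos)
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        # mirror image point at equal depth inside the fluid, plus a second
        # probe one h deeper (kept for diagnostics / richer reconstructions)
        b1 = np.maximum(depth, 0.05 * self.h)
        b2 = depth + self.h
        wall_pt = pos - depth[:, None] * nrm
        p1 = wall_pt - b1[:, None] * nrm
        p2 = wall_pt - b2[:, None] * nrm
        s1, w1 = self._trilinear_stencil(c, p1)
        s2, w2 = self._trilinear_stencil(c, p2)
        return GhostSet(index, depth, s1, w1, s2, w2, b1, b2)

    def apply_ghosts(self, fields: list[np.ndarray], n_iter: int = 2) -> None:
        """Reconstruct ghost-face velocities enforcing no-slip at the wall.

        Mirror-image reflection: ``u_ghost = -u(image)`` with the image point
        at equal depth inside the fluid, which vanishes exactly at the wall
        midpoint (second-order wall placement) and never amplifies interior
        values — the reflection is a pure interpolation, so the lagged
        (explicit) ghost update stays stable under large viscous numbers.
        Image interpolation may touch other ghost faces, hence the
        fixed-point iterations.  Deep solid faces are zeroed.
        """
        for c in range(3):
            gs = self.ghosts[c]
            u = fields[c]
            solid = ~self.face_fluid[c]
            u[solid] = 0.0
            if len(gs.index) == 0:
                continue
            gi = tuple(gs.index.T)
            scale = np.where(gs.depth > 0.05 * self.h,
                             gs.depth / gs.b1, 0.0)
            for _ in range(n_iter):
                u1 = (u[gs.stencil1[..., 0], gs.stencil1[..., 1],
                        gs.stencil1[..., 2]] * gs.weights1).sum(axis=1)
                u[gi] = -scale * u1

    # -- counts ------------------------------------------------------------
    @property
    def n_fluid_cells(self) -> int:
        return int(self.cell_fluid.sum())


def classify_grid(distance: DistanceField, h: float,
                  lo: np.ndarray | None = None,
                  hi: np.ndarray | None = None,
                  periodic_x: bool = False,
                  wall_lateral_faces: bool | None = None) -> EulerianGrid:
    """Build the staggered grid classification from a signed-distance field.

    In capped (non-periodic) boxes the lumen is intersected with the box
    interior by default: the four lateral box faces become solid walls, so
    vessels obliquely grazing a box edge are walled off rather than left
    with un-governed open faces — only the two x faces admit in/outflow.
    """
    if lo is None:
        lo = distance.origin
    if hi is None:
        hi = distance.origin + distance.h * (np.asarray(distance.shape) - 1)
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    shape = tuple(int(round((hi[ax] - lo[ax]) / h)) for ax in range(3))
    if min(shape) < 4:
        raise ValueError("grid box smaller than 4 cells in some direction")
    if wall_lateral_faces is None:
        wall_lateral_faces = not periodic_x
    if wall_lateral_faces:
        base = distance.fn if distance.fn is not None else distance.sample
        margin = 1.0 * h

        def clipped(points: np.ndarray) -> np.ndarray:
            pts = np.atleast_2d(points)
            d = np.asarray(base(pts), float).copy()
            for ax in (1, 2):
                d = np.maximum(d, (lo[ax] + margin) - pts[:, ax])
                d = np.maximum(d, pts[:, ax] - (hi[ax] - margin))
            return d

        distance = DistanceField(origin=distance.origin, h=distance.h,
                                 values=distance.values, fn=clipped)
    return EulerianGrid(origin=lo, h=h, shape=shape, periodic_x=periodic_x,
                        distance=distance)


def build_pressure_poisson(grid: EulerianGrid,
                           dirichlet_cells: np.ndarray | None = None):
    """Assemble and factorize the pressure Poisson operator on fluid cells.

    Links to solid neighbors are dropped (homogeneous Neumann at walls);
    optional Dirichlet cells (inlet/outlet caps) get identity rows.  With no
    Dirichlet cell the constant nullspace is removed by pinning one cell,
    which is exact for a compatible right-hand side.
    """
    nx, ny, nz = grid.shape
    fluid = grid.cell_fluid
    idx = -np.ones(grid.shape, dtype=np.int64)
    ids = np.argwhere(fluid)
    idx[fluid] = np.arange(len(ids))
    n = len(ids)
    diri = np.zeros(n, dtype=bool)
    if dirichlet_cells is not None:
        diri_mask = np.zeros(grid.shape, dtype=bool)
        diri_mask[tuple(dirichlet_cells.T)] = True
        diri = diri_mask[fluid]

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for ax, per in ((0, grid.periodic_x), (1, False), (2, False)):
        for sgn in (-1, 1):
            nb = np.roll(idx, -sgn, axis=ax) if per else _shift(idx, sgn, ax)
            nb_f = nb[fluid]
            here = idx[fluid]
            ok = (nb_f >= 0) & ~diri
            rows.append(here[ok])
            cols.append(nb_f[ok])
            vals.append(np.ones(ok.sum()))
            diag[here[ok]] -= 1.0
    rows.append(np.flatnonzero(diri))
    cols.append(np.flatnonzero(diri))
    vals.append(np.ones(diri.sum()))
    rows = np.concatenate(rows + [np.arange(n)[~diri]])
    cols = np.concatenate(cols + [np.arange(n)[~diri]])
    vals = np.concatenate(vals + [diag[~diri]])
    A = sparse.csr_matrix((vals / grid.h**2 / UM**2, (rows, cols)), shape=(n, n))
    if not diri.any():
        # pin cell 0 to remove the constant nullspace
        A = A.tolil()
        A.rows[0] = [0]
        A.data[0] = [1.0]
        A = A.tocsr()
    return splu(A.tocsc()), idx, diri


def _shift(arr: np.ndarray, sgn: int, ax: int) -> np.ndarray:
    out = np.full_like(arr, -1)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if sgn > 0:
        dst[ax] = slice(0, -1)
        src[ax] = slice(1, None)
    else:
        dst[ax] = slice(1, None)
        src[ax] = slice(0, -1)
    out[tuple(dst)] = arr[tuple(src)]
    return out
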