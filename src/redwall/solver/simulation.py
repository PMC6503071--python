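"""Run orchestration: RBC-laden or plasma-only runs with monitors.

``run_simulation`` advances the coupled membrane/fluid system, samples the
velocity field and cell states on the configured cadence (0.5 ms by
default), accumulates the running time averages used by the wall-stress
pipeline, and tracks conservation monitors (cell area/volume drift, flow
rate, divergence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from ..membrane.cell import UM, CellMembrane, area_volume
from ..membrane.seeding import Placement
from .grid import EulerianGrid
from .ibm import interpolate_velocity, spread_forces
from .stepper import BoundaryCondition, FlowState, StokesSolver
from .viscosity import MU_INTERIOR, MU_PLASMA, cell_indicator


class CellEnsemble:
    """All seeded cells share one template; forces evaluate in one batch."""

    def __init__(self, template: CellMembrane, placements: list[Placement]):
        self.template = template
        self.n_cells = len(placements)
        nv = template.n_vertices
        self.nv = nv
        self.vertices = np.concatenate([p.apply(template) for p in placements]) \
            if placements else np.zeros((0, 3))
        m = len(template.triangles)
        offs = (np.arange(self.n_cells) * nv)[:, None, None]
        self.triangles = (template.triangles[None] + offs).reshape(-1, 3) \
            if placements else np.zeros((0, 3), np.int64)
        self.ref_inv = np.tile(template.ref_inv, (self.n_cells, 1, 1))
        self.ref_area = np.tile(template.ref_area, self.n_cells)
        self.bend_L = sparse.block_diag([template.bend_L] * self.n_cells).tocsr() \
            if placements else None
        self.bend_A = np.tile(template.bend_A, self.n_cells)
        self._m = m

    def per_cell(self) -> list[np.ndarray]:
        return [self.vertices[i * self.nv:(i + 1) * self.nv]
                for i in range(self.n_cells)]

    def meshes(self) -> list[tuple[np.ndarray, np.ndarray]]:
        t = self.template.triangles
        return [(v, t) for v in self.per_cell()]

    def forces(self) -> np.ndarray:
        """Skalak + bending nodal forces (N) for all cells at once."""
        if self.n_cells == 0:
            return np.zeros((0, 3))
        t = self.template
        x = self.vertices * UM
        tri = x[self.triangles]
        D = np.stack([tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]], axis=2)
        F = D @ self.ref_inv
        G = np.einsum("mki,mkj->mij", F, F)
        detG = G[:, 0, 0] * G[:, 1, 1] - G[:, 0, 1] * G[:, 1, 0]
        bad = np.flatnonzero(detG <= 0)
        if len(bad):
            raise ValueError(f"degenerate deformed triangle id {bad[0]}")
        I1 = G[:, 0, 0] + G[:, 1, 1] - 2.0
        I2 = detG - 1.0
        W1 = 0.5 * t.G_s * (I1 + 1.0)
        W2 = 0.5 * t.G_s * (t.C_dil * I2 - 1.0)
        Ginv = np.empty_like(G)
        Ginv[:, 0, 0] = G[:, 1, 1]
        Ginv[:, 1, 1] = G[:, 0, 0]
        Ginv[:, 0, 1] = -G[:, 0, 1]
        Ginv[:, 1, 0] = -G[:, 1, 0]
        Ginv /= detG[:, None, None]
        dEdF = self.ref_area[:, None, None] * (
            2.0 * W1[:, None, None] * F
            + 2.0 * (W2 * detG)[:, None, None] * (F @ Ginv))
        P = dEdF @ np.transpose(self.ref_inv, (0, 2, 1))
        f = np.zeros_like(self.vertices)
        np.add.at(f, self.triangles[:, 1], -P[:, :, 0])
        np.add.at(f, self.triangles[:, 2], -P[:, :, 1])
        np.add.at(f, self.triangles[:, 0], P[:, :, 0] + P[:, :, 1])
        # bending (frozen-weight Helfrich operator, current vertex areas)
        from ..membrane.bending import _bending_force_arrays

        f += _bending_force_arrays(t, self.bend_L, self.triangles, x)
        return f

    def area_volume_per_cell(self) -> list[tuple[float, float]]:
        return [area_volume(v, self.template.triangles) for v in self.per_cell()]


#: short-range repulsion (standard immersed-boundary suspension guard
#: against under-resolved lubrication): quadratic ramp inside the cutoff
REPULSION_CUTOFF_WALL = 0.3   # µm
REPULSION_CUTOFF_CELL = 0.3   # µm
REPULSION_FMAX = 2e-11        # N per vertex at full compression


def repulsion_forces(ens: CellEnsemble, distance) -> np.ndarray:
    """Wall and cell-cell contact forces on membrane vertices (N).

    Lubrication films thinner than the grid spacing are under-resolved by
    the 4-point kernel, so membranes are kept apart by a short-range
    quadratic repulsion: against the wall along the inward distance
    gradient, and pairwise (equal and opposite) between vertices of
    different cells.
    """
    from scipy.spatial import cKDTree

    f = np.zeros_like(ens.vertices)
    v = ens.vertices
    # wall
    phi = distance.sample(v)
    near = phi > -REPULSION_CUTOFF_WALL
    if near.any():
        g = distance.gradient(v[near])
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        x = np.clip(1.0 + phi[near] / REPULSION_CUTOFF_WALL, 0.0, None)
        # overlap (phi > 0) keeps ramping so penetrated vertices are pushed
        # back harder than surface-adjacent ones
        f[near] -= REPULSION_FMAX * (x**2)[:, None] * g
    # cell-cell
    if ens.n_cells > 1:
        tree = cKDTree(v)
        pairs = tree.query_pairs(REPULSION_CUTOFF_CELL, output_type="ndarray")
        if len(pairs):
            ci = pairs[:, 0] // ens.nv
            cj = pairs[:, 1] // ens.nv
            pairs = pairs[ci != cj]
        if len(pairs):
            d = v[pairs[:, 0]] - v[pairs[:, 1]]
            r = np.linalg.norm(d, axis=1)
            r = np.where(r < 1e-9, 1e-9, r)
            mag = REPULSION_FMAX * (1.0 - r / REPULSION_CUTOFF_CELL) ** 2
            fv = (mag / r)[:, None] * d
            np.add.at(f, pairs[:, 0], fv)
            np.add.at(f, pairs[:, 1], -fv)
    return f


@dataclass
class SimulationConfig:
    """Study conditions for one run (defaults are the desk-scale fixture)."""

    h: float = 0.5                 # grid spacing, µm
    dt: float | None = None        # s; None -> stable_dt
    t_end: float = 0.02            # s
    sample_dt: float = 5e-4        # s, snapshot/averaging cadence
    bc_kind: str = "pressure_drop"
    bc_value: float = 0.1          # Pa/µm or m³/s
    hematocrit: float = 0.0
    seed: int = 0
    n_refine: int = 3              # membrane subdivision for seeded cells
    rho: float = 1000.0
    mu_plasma: float = MU_PLASMA
    mu_interior: float = MU_INTERIOR
    periodic_x: bool = True
    store_snapshots: bool = True
    recycle: bool = True           # reinsert cells leaving a capped outlet
    #: refresh the viscosity indicator every this many steps: membrane
    #: displacement per step is ~1e-3 grid cells, so a short lag is inert
    mu_update_every: int = 10


@dataclass
class RunResult:
    config: SimulationConfig
    grid: EulerianGrid
    solver: StokesSolver
    state: FlowState
    mean_u: list[np.ndarray]            # time-averaged face velocities, m/s
    mean_indicator: np.ndarray          # time-averaged cell indicator
    sample_times: list[float]
    snapshots_u: list[list[np.ndarray]] = field(default_factory=list)
    cell_snapshots: list[np.ndarray] = field(default_factory=list)
    monitors: dict = field(default_factory=dict)
    placements: list[Placement] = field(default_factory=list)
    ensemble: CellEnsemble | None = None
    status: str = "ok"

    @property
    def n_samples(self) -> int:
        return len(self.sample_times)

    def area_volume_drift(self) -> tuple[float, float]:
        """Max relative |drift| of cell area and volume over the run."""
        mon = self.monitors
        if not mon.get("cell_area"):
            return 0.0, 0.0
        a = np.asarray(mon["cell_area"])
        v = np.asarray(mon["cell_volume"])
        da = np.abs(a / a[0] - 1.0).max()
        dv = np.abs(v / v[0] - 1.0).max()
        return float(da), float(dv)


def run_simulation(grid: EulerianGrid, config: SimulationConfig,
                   placements: list[Placement] | None = None,
                   template: CellMembrane | None = None) -> RunResult:
    """Advance the coupled system from rest to ``t_end``; see module doc."""
    bc = BoundaryCondition(config.bc_kind, config.bc_value)
    sol = StokesSolver(grid, bc, rho=config.rho, mu_plasma=config.mu_plasma)
    if not grid.periodic_x and bc.kind == "inlet_flow_rate":
        sol.set_inlet_profile()
    placements = placements or []
    if placements and template is None:
        from ..membrane.cell import make_biconcave

        template = make_biconcave(n_refine=config.n_refine)
    ens = CellEnsemble(template, placements) if placements else None

    dt = config.dt
    if dt is None:
        dt = sol.stable_dt(has_cells=bool(placements),
                           G_s=template.G_s if template else 2.5e-6,
                           k_b=template.k_b if template else 2.7e-19,
                           mu_contrast=config.mu_interior / config.mu_plasma)
    n_steps = int(np.ceil(config.t_end / dt))
    sample_every = max(1, int(round(config.sample_dt / dt)))

    state = sol.initial_state()
    mean_u = [np.zeros_like(a) for a in state.u]
    mean_ind = np.zeros(grid.shape)
    res = RunResult(config=config, grid=grid, solver=sol, state=state,
                    mean_u=mean_u, mean_indicator=mean_ind, sample_times=[],
                    placements=placements, ensemble=ens)
    mon: dict[str, list] = {"t": [], "flow_rate": [], "divergence": [],
                            "cell_area": [], "cell_volume": [],
                            "body_force": []}
    res.monitors = mon
    n_avg = 0
    Lx = grid.box_length[0]

    from .ibm import kernel_stencils

    ind = np.zeros(grid.shape)
    for it in range(n_steps):
        stencils = None
        if ens is not None:
            if not np.isfinite(ens.vertices).all():
                res.status = f"aborted: NaN in cell vertices at t={state.t:.3e}s"
                break
            if it % max(1, config.mu_update_every) == 0:
                ind = cell_indicator(grid, ens.meshes(), check_closed=False)
                state.mu = config.mu_plasma + (config.mu_interior
                                               - config.mu_plasma) * ind
            try:
                f_nodes = ens.forces()
                f_nodes += repulsion_forces(ens, grid.distance)
                wrapped = _wrap_x(ens.vertices, grid)
                stencils = kernel_stencils(grid, wrapped)
                state.f = spread_forces(grid, wrapped, f_nodes,
                                        stencils=stencils)
            except ValueError as err:
                res.status = f"aborted at t={state.t:.3e}s: {err}"
                break
        sol.step(state, dt)
        if ens is not None:
            vel = interpolate_velocity(grid, state.u,
                                       _wrap_x(ens.vertices, grid),
                                       stencils=stencils)
            ens.vertices += (dt / UM) * vel
            if grid.periodic_x:
                _rewrap_cells(ens, grid, Lx)
            elif config.recycle:
                _recycle_cells(ens, grid, config.seed + it)
        if (it + 1) % sample_every == 0:
            if not all(np.isfinite(a).all() for a in state.u):
                res.status = f"aborted: NaN detected at t={state.t:.3e}s"
                break
            n_avg += 1
            for c in range(3):
                mean_u[c] += (state.u[c] - mean_u[c]) / n_avg
            ind_now = ind if ens is not None else np.zeros(grid.shape)
            mean_ind += (ind_now - mean_ind) / n_avg
            res.sample_times.append(state.t)
            if config.store_snapshots:
                res.snapshots_u.append([a.copy() for a in state.u])
                if ens is not None:
                    res.cell_snapshots.append(ens.vertices.copy())
            mon["t"].append(state.t)
            mon["flow_rate"].append(sol.flow_rate(state.u))
            mon["divergence"].append(sol.last_divergence)
            mon["body_force"].append(sol.body_force)
            if ens is not None:
                av = ens.area_volume_per_cell()
                mon["cell_area"].append(sum(a for a, _ in av))
                mon["cell_volume"].append(sum(v for _, v in av))
    return res


def _wrap_x(verts: np.ndarray, grid: EulerianGrid) -> np.ndarray:
    out = verts.copy()
    Lx = grid.box_length[0]
    out[:, 0] = grid.origin[0] + np.mod(out[:, 0] - grid.origin[0], Lx)
    return out


def _rewrap_cells(ens: CellEnsemble, grid: EulerianGrid, Lx: float) -> None:
    """Keep each cell's coordinates unwrapped but near the box (shift whole
    cells by one period when their centroid leaves)."""
    for i in range(ens.n_cells):
        v = ens.vertices[i * ens.nv:(i + 1) * ens.nv]
        cx = v[:, 0].mean()
        if cx < grid.origin[0]:
            v[:, 0] += Lx
        elif cx >= grid.origin[0] + Lx:
            v[:, 0] -= Lx


def _recycle_cells(ens: CellEnsemble, grid: EulerianGrid, seed: int) -> None:
    """Reinsert a cell whose centroid left the outlet cap at the inlet with
    its current shape, at a seeded random off-axis position."""
    rng = np.random.default_rng(seed % (2**31 - 1))
    x_out = grid.origin[0] + grid.box_length[0]
    for i in range(ens.n_cells):
        v = ens.vertices[i * ens.nv:(i + 1) * ens.nv]
        c = v.mean(axis=0)
        if c[0] < x_out - grid.h:
            continue
        for _ in range(50):
            shift = np.zeros(3)
            shift[0] = grid.origin[0] + 2.5 * grid.h
            shift[1:] = c[1:] + rng.normal(scale=grid.h, size=2)
            cand = v - c + shift + np.array([np.ptp(v[:, 0]) / 2, 0, 0])
            if grid.distance.sample(cand).max() < -0.1:
                v[:] = cand
                break


__all__ = ["CellEnsemble", "RunResult", "SimulationConfig", "run_simulation"]
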