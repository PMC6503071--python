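"""Unsteady Stokes time stepping: semi-implicit ADI viscous solve plus
pressure projection, with sharp-interface ghost-node walls.

One step advances

    rho du/dt = -grad p + div(mu grad u) + f,   div u = 0

by a delta-form Douglas-Gunn ADI factorization of backward Euler for the
directionally split viscous operator (so the converged steady state solves
the unsplit discrete momentum equation exactly), followed by an incremental
pressure projection on the fluid cells.  No-slip on the curved wall is
enforced by quadratic image-point reflection onto ghost faces; the
projection treats wall-adjacent face velocities as boundary data, so the
discrete divergence on fluid cells vanishes to solver precision.

Inertia is retained only as the unsteady term: the convective term is
omitted (Re << 1 in the microcirculation).  The transpose part of the
variable-viscosity stress is omitted as well; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .grid import EulerianGrid, UM

RHO_DEFAULT = 1000.0  # kg/m³


@dataclass
class BoundaryCondition:
    """Exactly one driving mechanism per run.

    kind = "pressure_drop": value is the axial pressure gradient in Pa/µm
    (realized as an equivalent uniform body force in periodic boxes, or as
    Dirichlet cap pressures in capped boxes).
    kind = "inlet_flow_rate": value is the volumetric rate in m³/s through
    the feeding vessel (feedback-controlled body force in periodic boxes, or
    a prescribed inlet profile in capped boxes).
    """

    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("pressure_drop", "inlet_flow_rate"):
            raise ValueError(f"unknown boundary-condition kind {self.kind!r}")


@dataclass
class FlowState:
    """Velocity/pressure/viscosity fields at one instant (SI units)."""

    u: list[np.ndarray]       # face velocities, m/s
    p: np.ndarray             # cell pressure, Pa
    mu: np.ndarray            # cell viscosity, Pa s
    f: list[np.ndarray]       # IBM body-force density, N/m³
    t: float = 0.0

    def copy(self) -> "FlowState":
        return FlowState([a.copy() for a in self.u], self.p.copy(),
                         self.mu.copy(), [a.copy() for a in self.f], self.t)


def _tridiag(a, b, c, d):
    """Thomas solve along axis 0, batched over trailing axes (in place)."""
    n = d.shape[0]
    cp = np.empty_like(d)
    dp = np.empty_like(d)
    cp[0] = c[0] / b[0]
    dp[0] = d[0] / b[0]
    for i in range(1, n):
        m = b[i] - a[i] * cp[i - 1]
        cp[i] = c[i] / m
        dp[i] = (d[i] - a[i] * dp[i - 1]) / m
    x = dp
    for i in range(n - 2, -1, -1):
        x[i] -= cp[i] * x[i + 1]
    return x


def _tridiag_periodic(a, b, c, d):
    """Cyclic tridiagonal solve (Sherman-Morrison), axis 0, batched."""
    n = d.shape[0]
    if n < 3:
        raise ValueError("periodic tridiagonal needs n >= 3")
    gamma = -b[0]
    bb = b.copy()
    bb[0] = b[0] - gamma
    bb[-1] = b[-1] - a[0] * c[-1] / gamma
    y = _tridiag(a, bb, c, d.copy())
    q = np.zeros_like(d)
    q[0] = gamma
    q[-1] = c[-1]
    z = _tridiag(a, bb, c, q)
    fact = (y[0] + a[0] * y[-1] / gamma) / (1.0 + z[0] + a[0] * z[-1] / gamma)
    return y - fact * z


class StokesSolver:
    """Projection/ADI integrator bound to one classified grid."""

    def __init__(self, grid: EulerianGrid, bc: BoundaryCondition,
                 rho: float = RHO_DEFAULT, mu_plasma: float = 0.001,
                 flow_relax: float = 0.4):
        self.grid = grid
        self.bc = bc
        self.rho = rho
        self.mu_plasma = mu_plasma
        self.flow_relax = flow_relax
        self.h_m = grid.h * UM
        self.body_force = 0.0  # N/m³ along +x, evolves under flow-rate control
        if bc.kind == "pressure_drop":
            if not grid.periodic_x:
                raise NotImplementedError(
                    "pressure-drop runs use the periodic axial box")
            self.body_force = bc.value * 1e6  # Pa/µm -> Pa/m
        self._build_masks()
        self._build_poisson()
        self._cap_inflow: np.ndarray | None = None
        self._mu_cache_key = None
        self._visc_coeffs: dict[tuple[int, int], np.ndarray] = {}
        self.last_divergence = 0.0
        self.residual_history: list[float] = []

    # ------------------------------------------------------------------ setup
    def _build_masks(self) -> None:
        g = self.grid
        fluid = g.cell_fluid
        self.link = []   # per component: faces corrected by the projection
        self.flux = []   # per component: faces carrying mass flux
        for c in range(3):
            fs = g.face_shape(c)
            lo = np.zeros(fs, dtype=bool)   # fluid cell on the low side
            hi = np.zeros(fs, dtype=bool)
            if c == 0 and g.periodic_x:
                lo[:] = np.roll(fluid, 1, axis=0)
                hi[:] = fluid
            else:
                sl_lo = [slice(None)] * 3
                sl_hi = [slice(None)] * 3
                sl_lo[c] = slice(1, None)
                sl_hi[c] = slice(0, -1)
                lo[tuple(sl_lo)] = fluid
                hi[tuple(sl_hi)] = fluid
            link = lo & hi & g.face_fluid[c]
            self.link.append(link)
            # mass flux crosses linked faces only: wall (ghost) faces carry
            # the no-slip reconstruction for the viscous stencils but zero
            # flux, so the staircase lumen is exactly conservative.  Cap
            # faces (inlet data, Dirichlet-pressure outlet) do carry flux.
            fluxmask = link.copy()
            if c == 0 and not g.periodic_x:
                fluxmask[0] |= g.face_fluid[0][0] & fluid[0]
                fluxmask[-1] |= g.face_fluid[0][-1] & fluid[-1]
            self.flux.append(fluxmask)

    def _build_poisson(self) -> None:
        g = self.grid
        self._poisson_fft = None
        # capped boxes drain through a zero-pressure outlet at the high-x
        # face: those cap faces join the projection against a mirrored
        # pressure ghost, which makes the system nonsingular and lets wall
        # and transient mass imbalances leave through the outlet
        self._outlet_mask = None
        self._poisson_pinned = True
        if not g.periodic_x:
            self._outlet_mask = g.face_fluid[0][-1] & g.cell_fluid[-1]
        if g.periodic_x and bool(np.all(g.cell_fluid == g.cell_fluid[:1])) \
                and bool(np.all(self.link[1] == self.link[1][:1])) \
                and bool(np.all(self.link[2] == self.link[2][:1])):
            self._build_poisson_fft()
            return
        fluid = g.cell_fluid
        idx = -np.ones(g.shape, dtype=np.int64)
        n = int(fluid.sum())
        idx[fluid] = np.arange(n)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        for c in range(3):
            link = self.link[c]
            if c == 0 and g.periodic_x:
                lo_idx = np.roll(idx, 1, axis=0)
                hi_idx = idx
                lf = link
                a = lo_idx[lf]
                b = hi_idx[lf]
            else:
                sl_int = [slice(None)] * 3
                sl_int[c] = slice(1, -1) if link.shape[c] == g.shape[c] + 1 \
                    else slice(None)
                lf = link[tuple(sl_int)]
                lo_idx = idx[tuple(_sl(c, slice(0, -1)))]
                hi_idx = idx[tuple(_sl(c, slice(1, None)))]
                a = lo_idx[lf]
                b = hi_idx[lf]
            rows += [a, b]
            cols += [b, a]
            vals += [np.ones(len(a)), np.ones(len(b))]
            np.add.at(diag, a, -1.0)
            np.add.at(diag, b, -1.0)
        pinned = True
        if self._outlet_mask is not None and self._outlet_mask.any():
            out_cells = idx[-1][self._outlet_mask]
            np.add.at(diag, out_cells, -2.0)  # p ghost = -p at the cap face
            pinned = False
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        A = sparse.csr_matrix(
            (np.concatenate(vals) / self.h_m**2,
             (np.concatenate(rows), np.concatenate(cols))), shape=(n, n))
        if pinned:
            A = A.tolil()
            A.rows[0] = [0]
            A.data[0] = [1.0]
        self._poisson_pinned = pinned
        self._poisson_lu = splu(A.tocsc())
        self._cell_index = idx

    def _build_poisson_fft(self) -> None:
        """x-invariant periodic geometry: diagonalize the Poisson operator by
        FFT along x and factorize one small 2D system per wavenumber."""
        g = self.grid
        nx = g.shape[0]
        fluid2 = g.cell_fluid[0]                      # (ny, nz)
        idx2 = -np.ones(fluid2.shape, dtype=np.int64)
        n2 = int(fluid2.sum())
        idx2[fluid2] = np.arange(n2)
        rows, cols, vals = [], [], []
        diag = np.zeros(n2)
        for c in (1, 2):
            link2 = self.link[c][0]                   # faces in the yz plane
            ax = c - 1
            lf = np.take(link2, range(1, link2.shape[ax] - 0 - 1), axis=ax) \
                if link2.shape[ax] == fluid2.shape[ax] + 1 else link2
            lo = np.take(idx2, range(0, fluid2.shape[ax] - 1), axis=ax)
            hi = np.take(idx2, range(1, fluid2.shape[ax]), axis=ax)
            a = lo[lf]
            b = hi[lf]
            rows += [a, b]
            cols += [b, a]
            vals += [np.ones(len(a)), np.ones(len(b))]
            np.add.at(diag, a, -1.0)
            np.add.at(diag, b, -1.0)
        rows.append(np.arange(n2))
        cols.append(np.arange(n2))
        vals.append(diag)
        A2 = sparse.csr_matrix(
            (np.concatenate(vals) / self.h_m**2,
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n2, n2)).tocsc()
        lam = (2.0 * np.cos(2.0 * np.pi * np.arange(nx // 2 + 1) / nx) - 2.0) \
            / self.h_m**2
        eye = sparse.identity(n2, format="csc")
        lus = []
        for k, lk in enumerate(lam):
            Ak = A2 + lk * eye
            if k == 0:
                Ak = Ak.tolil()
                Ak.rows[0] = [0]
                Ak.data[0] = [1.0]
                Ak = Ak.tocsc()
            lus.append(splu(Ak))
        self._poisson_fft = (lus, idx2, n2)

    def _solve_poisson(self, rhs3: np.ndarray) -> np.ndarray:
        """Solve the pressure Poisson problem; rhs and result on cells."""
        g = self.grid
        out = np.zeros(g.shape)
        if self._poisson_fft is not None:
            lus, idx2, n2 = self._poisson_fft
            fluid2 = g.cell_fluid[0]
            r = rhs3[:, fluid2]                       # (nx, n2)
            rh = np.fft.rfft(r, axis=0)
            sol = np.empty_like(rh)
            for k, lu in enumerate(lus):
                b_re = rh[k].real.copy()
                b_im = rh[k].imag.copy()
                if k == 0:
                    b_re[0] = 0.0
                    b_im[0] = 0.0
                sol[k] = lu.solve(b_re) + 1j * lu.solve(b_im)
            p = np.fft.irfft(sol, n=g.shape[0], axis=0)
            out[:, fluid2] = p
            return out
        rhs_p = rhs3[g.cell_fluid]
        if self._poisson_pinned:
            rhs_p[0] = 0.0  # pinned cell
        out[g.cell_fluid] = self._poisson_lu.solve(rhs_p)
        return out

    # ------------------------------------------------------------ operators
    def divergence(self, u: list[np.ndarray]) -> np.ndarray:
        g = self.grid
        d = np.zeros(g.shape)
        for c in range(3):
            f = u[c] * self.flux[c]
            if c == 0 and g.periodic_x:
                d += (np.roll(f, -1, axis=0) - f) / self.h_m
            else:
                d += (f[tuple(_sl(c, slice(1, None)))]
                      - f[tuple(_sl(c, slice(0, -1)))]) / self.h_m
        d[~g.cell_fluid] = 0.0
        return d

    def _grad_p(self, p: np.ndarray, c: int) -> np.ndarray:
        g = self.grid
        out = np.zeros(g.face_shape(c))
        if c == 0 and g.periodic_x:
            out[:] = (p - np.roll(p, 1, axis=0)) / self.h_m
        else:
            out[tuple(_sl(c, slice(1, -1)))] = np.diff(p, axis=c) / self.h_m
        return out

    def _visc_coeff(self, mu: np.ndarray, c: int, d: int) -> np.ndarray:
        """Viscosity between consecutive faces of component c along axis d.

        Along axis d the array has one entry per face gap: cell-count length
        with wraparound on the periodic axis, cell-count - 1 otherwise.
        ``d == c`` gaps sit at cell centers; ``d != c`` gaps sit at edges and
        use the harmonic mean of the four surrounding cells.
        """
        if d == c:
            return mu
        per_x = self.grid.periodic_x
        m = _face_harm(mu, c, per=(c == 0 and per_x))
        return _mid_harm(m, d, per=(d == 0 and per_x))

    # ---------------------------------------------------------------- step
    def stable_dt(self, has_cells: bool, G_s: float = 2.5e-6,
                  k_b: float = 2.7e-19, mu_contrast: float = 5.0,
                  accuracy_cap: float = 2.5e-5,
                  safety: float = 0.5) -> float:
        """Admissible time step (s): membrane-elastic and bending explicit
        constraints (safety-factored), or the accuracy cap for plasma only.

        The interior/plasma viscosity contrast tightens the membrane bound
        (empirically ~1/sqrt(contrast) at contrast 5); the leading constants
        were calibrated once against a bisection blow-up scan of the coupled
        tube run at the default moduli and h = 0.5 µm.
        """
        if not has_cells:
            return accuracy_cap
        h = self.h_m
        dt_mem = 0.4 * h * np.sqrt(self.rho * h / G_s)
        dt_mem /= np.sqrt(max(mu_contrast, 1.0))
        dt_bend = 0.5 * h**2 * np.sqrt(self.rho * h / k_b)
        return safety * min(dt_mem, dt_bend, accuracy_cap / safety)

    def initial_state(self) -> FlowState:
        g = self.grid
        u = [np.zeros(g.face_shape(c)) for c in range(3)]
        f = [np.zeros(g.face_shape(c)) for c in range(3)]
        mu = np.full(g.shape, self.mu_plasma)
        return FlowState(u=u, p=np.zeros(g.shape), mu=mu, f=f, t=0.0)

    def _adi_coeffs(self, mu: np.ndarray):
        key = id(mu)
        if self._mu_cache_key != key:
            self._visc_coeffs = {
                (c, d): self._visc_coeff(mu, c, d)
                for c in range(3) for d in range(3)}
            self._mu_cache_key = key
        return self._visc_coeffs

    def _viscous_rhs(self, u: list[np.ndarray], coeffs) -> list[np.ndarray]:
        """div(mu grad u_c), all directions, explicit evaluation."""
        out = []
        h2 = self.h_m**2
        per = self.grid.periodic_x
        for c in range(3):
            f = u[c]
            acc = np.zeros_like(f)
            for d in range(3):
                m = coeffs[(c, d)]
                if d == 0 and per:
                    fp = np.roll(f, -1, axis=0)
                    fm = np.roll(f, 1, axis=0)
                    mp = m
                    mm = np.roll(m, 1, axis=0)
                    acc += (mp * (fp - f) - mm * (f - fm)) / h2
                else:
                    # interior second difference; one-sided rows stay zero
                    fi = np.moveaxis(f, d, 0)
                    mi = np.moveaxis(m, d, 0)
                    lap = np.zeros_like(fi)
                    lap[1:-1] = (mi[1:] * (fi[2:] - fi[1:-1])
                                 - mi[:-1] * (fi[1:-1] - fi[:-2])) / h2
                    acc += np.moveaxis(lap, 0, d)
            out.append(acc)
        return out

    def _adi_solve(self, rhs: list[np.ndarray], coeffs, dt: float
                   ) -> list[np.ndarray]:
        """(I - dt/rho Ax)(I - dt/rho Ay)(I - dt/rho Az) du = rhs."""
        lam = dt / (self.rho * self.h_m**2)
        per = self.grid.periodic_x
        out = []
        for c in range(3):
            x = rhs[c]
            fluid = self.grid.face_fluid[c]
            for d in range(3):
                m = coeffs[(c, d)]
                xd = np.moveaxis(x, d, 0).copy()
                md = np.moveaxis(m, d, 0)
                fd = np.moveaxis(fluid, d, 0)
                n = xd.shape[0]
                if d == 0 and per:
                    mp = md.astype(float).copy()
                    mm = np.roll(md, 1, axis=0).copy()
                else:
                    mp = np.zeros_like(xd)
                    mm = np.zeros_like(xd)
                    mp[: n - 1] = md
                    mm[1:] = md
                # ghost/solid neighbors are frozen (Dirichlet) in the solve:
                # drop their off-diagonal links, keep the diagonal damping
                nb_lo = np.roll(fd, 1, axis=0) if (d == 0 and per) else \
                    np.concatenate([fd[:1] & False, fd[:-1]], axis=0)
                nb_hi = np.roll(fd, -1, axis=0) if (d == 0 and per) else \
                    np.concatenate([fd[1:], fd[:1] & False], axis=0)
                a = np.where(nb_lo, -lam * mm, 0.0)
                cc = np.where(nb_hi, -lam * mp, 0.0)
                bdiag = 1.0 + lam * (mp + mm)
                a[~fd] = 0.0
                cc[~fd] = 0.0
                bdiag[~fd] = 1.0
                n_lines = xd.shape[0]
                flat = lambda arr: np.ascontiguousarray(
                    arr.reshape(n_lines, -1))
                if d == 0 and per:
                    from ._kernels import tridiag_periodic_batch

                    xd = tridiag_periodic_batch(
                        flat(a), flat(bdiag), flat(cc),
                        flat(xd)).reshape(xd.shape)
                else:
                    from ._kernels import tridiag_batch

                    xd = tridiag_batch(flat(a), flat(bdiag), flat(cc),
                                       flat(xd)).reshape(xd.shape)
                x = np.moveaxis(xd, 0, d)
            out.append(x)
        return out

    def step(self, state: FlowState, dt: float) -> FlowState:
        """Advance one time step in place; returns the same state object."""
        g = self.grid
        coeffs = self._adi_coeffs(state.mu)
        visc = self._viscous_rhs(state.u, coeffs)
        if self.bc.kind == "inlet_flow_rate" and g.periodic_x:
            self._update_flow_control(state, dt)
        rhs = []
        for c in range(3):
            r = (-self._grad_p(state.p, c) + visc[c] + state.f[c]) / self.rho
            if c == 0:
                r = r + self.body_force / self.rho
            r[~g.face_fluid[c]] = 0.0
            rhs.append(dt * r)
        du = self._adi_solve(rhs, coeffs, dt)
        for c in range(3):
            state.u[c] += du[c]
        g.apply_ghosts(state.u)
        if self._cap_inflow is not None:
            state.u[0][0] = self._cap_inflow
            state.u[0][-1] = state.u[0][-2]  # provisional outflow guess
        div = self.divergence(state.u)
        pfield = self._solve_poisson((self.rho / dt) * div)
        for c in range(3):
            gp = self._grad_p(pfield, c)
            state.u[c] -= (dt / self.rho) * gp * self.link[c]
        if self._outlet_mask is not None and self._outlet_mask.any():
            # outlet cap faces drain against the mirrored zero-pressure ghost
            m = self._outlet_mask
            state.u[0][-1][m] += (dt / self.rho) * 2.0 * pfield[-1][m] / self.h_m
        state.p += pfield
        state.t += dt
        dchk = self.divergence(state.u)
        umax = max(np.abs(state.u[c]).max() for c in range(3)) + 1e-300
        self.last_divergence = float(np.abs(dchk).max() / (umax / self.h_m))
        self.residual_history.append(self.last_divergence)
        return state

    def _update_flow_control(self, state: FlowState, dt: float) -> None:
        Q = self.flow_rate(state.u)
        A_lumen = self.grid.face_fluid[0][0].sum() * self.h_m**2
        if A_lumen == 0:
            raise ValueError("no fluid faces at the flow-metering plane")
        err = self.bc.value - Q
        self.body_force += self.flow_relax * self.rho * err / (A_lumen * dt)

    def flow_rate(self, u: list[np.ndarray], i_plane: int = 0) -> float:
        """Volumetric rate (m³/s) through the x-face plane ``i_plane``
        (flux-carrying faces only; ghost faces hold mirrored values)."""
        mask = self.flux[0][i_plane]
        return float(u[0][i_plane][mask].sum() * self.h_m**2)

    def set_inlet_profile(self) -> None:
        """Capped-box flow-rate BC: prescribe a Poiseuille-like inlet profile
        scaled to the requested rate on the inlet cap (x = 0 faces)."""
        if self.grid.periodic_x:
            raise ValueError("inlet profiles apply to capped boxes only")
        if self.bc.kind != "inlet_flow_rate":
            raise ValueError("inlet profile requires the flow-rate BC")
        g = self.grid
        centers = g.face_centers(0)[0].reshape(-1, 3)
        s = -g.distance.sample(centers)  # wall distance, µm (positive inside)
        s = np.clip(s, 0.0, None).reshape(g.shape[1], g.shape[2])
        R = s.max()
        w = s * (2.0 * R - s)
        w[~g.face_fluid[0][0]] = 0.0
        total = w.sum() * self.h_m**2
        self._cap_inflow = w * (self.bc.value / total)

    # ------------------------------------------------------------ steady run
    def run_to_steady(self, state: FlowState, dt: float,
                      tol: float = 1e-8, max_steps: int = 5000,
                      check_every: int = 10) -> FlowState:
        """March to a time-independent solution: ||u(t+Δ)-u(t)||/||u|| <= tol."""
        prev = None
        for it in range(max_steps):
            self.step(state, dt)
            if it % check_every == check_every - 1:
                cur = np.concatenate([state.u[c].ravel() for c in range(3)])
                if prev is not None:
                    nrm = np.linalg.norm(cur) + 1e-300
                    if np.linalg.norm(cur - prev) / nrm <= tol:
                        return state
                prev = cur
        return state


def _sl(axis: int, s: slice, ndim_axis: int | None = None):
    out = [slice(None)] * 3
    out[axis] = s
    return tuple(out)


def _harm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 2.0 * a * b / (a + b)


def _face_harm(m: np.ndarray, axis: int, per: bool) -> np.ndarray:
    """Cell array -> face positions along ``axis`` (harmonic pairwise)."""
    if per:
        return _harm(m, np.roll(m, 1, axis=axis))
    pad_lo = np.take(m, [0], axis=axis)
    pad_hi = np.take(m, [m.shape[axis] - 1], axis=axis)
    mp = np.concatenate([pad_lo, m, pad_hi], axis=axis)
    n = mp.shape[axis]
    return _harm(np.take(mp, range(0, n - 1), axis=axis),
                 np.take(mp, range(1, n), axis=axis))


def _mid_harm(m: np.ndarray, axis: int, per: bool) -> np.ndarray:
    """Between consecutive entries along ``axis`` (harmonic pairwise)."""
    if per:
        return _harm(m, np.roll(m, -1, axis=axis))
    n = m.shape[axis]
    return _harm(np.take(m, range(0, n - 1), axis=axis),
                 np.take(m, range(1, n), axis=axis))
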