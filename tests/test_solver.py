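"""Flow solver: classification, IBM kernels, viscosity field, projection,
Poiseuille accuracy and grid convergence."""

import numpy as np
import pytest

from redwall.geometry import make_tube, signed_distance
from redwall.geometry.sdf import DistanceField
from redwall.membrane import make_biconcave
from redwall.solver import (BoundaryCondition, StokesSolver, classify_grid,
                            interpolate_velocity, peskin4, spread_forces,
                            viscosity_field)
from redwall.solver.ibm import _kernel_stencil


class TestClassification:
    def test_fluid_cell_count_matches_cylinder_volume(self, tube_geometry):
        _, _, _, grid = tube_geometry
        expect = np.pi * 5.0**2 * 24.0 / grid.h**3
        assert grid.n_fluid_cells == pytest.approx(expect, rel=0.05)

    def test_all_solid_rejected(self):
        fn = lambda pts: np.full(len(np.atleast_2d(pts)), 5.0)
        df = DistanceField(origin=np.zeros(3), h=0.5,
                           values=np.full((9, 9, 9), 5.0), fn=fn)
        with pytest.raises(ValueError, match="no fluid cells|thinner"):
            classify_grid(df, 0.5, lo=np.zeros(3), hi=np.full(3, 4.0))

    def test_ghost_image_points_lie_in_fluid(self, tube_geometry):
        _, _, df, grid = tube_geometry
        for c in range(3):
            gs = grid.ghosts[c]
            if len(gs.index) == 0:
                continue
            # the stencil of the mirror probe must carry usable weight on
            # fluid faces (the probe itself sits inside the lumen)
            from redwall.solver.grid import face_offsets

            off = face_offsets(c)
            pos = grid.origin + grid.h * (gs.index + off)
            nrm = grid.distance.gradient(pos)
            nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
            img = pos - (gs.depth + gs.b1)[:, None] * nrm
            phi = grid.distance.sample(img)
            assert (phi < grid.h).all()
            deep = gs.depth > 0.3 * grid.h
            assert (phi[deep] < 0).all()


class TestIBMKernel:
    def test_partition_of_unity(self, tube_geometry):
        _, _, _, grid = tube_geometry
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(2, 22, 50),
                               rng.uniform(-3, 3, 50),
                               rng.uniform(-3, 3, 50)])
        for c in range(3):
            *_, w = _kernel_stencil(grid, c, pts)
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_spreading_conserves_total_force(self, tube_geometry):
        _, _, _, grid = tube_geometry
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(2, 22, 30),
                               rng.uniform(-3, 3, 30),
                               rng.uniform(-3, 3, 30)])
        f = rng.normal(size=(30, 3)) * 1e-12
        F = spread_forces(grid, pts, f)
        h3 = (grid.h * 1e-6) ** 3
        for c in range(3):
            assert F[c].sum() * h3 == pytest.approx(f[:, c].sum(), rel=1e-12)

    def test_linear_field_interpolated_exactly(self, tube_geometry):
        _, _, _, grid = tube_geometry
        a = np.array([0.3, -0.2, 0.5])
        b = 1.7e-4
        u = []
        for c in range(3):
            x = grid.face_centers(c)
            u.append(b + x @ a * 1e-5)
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.uniform(4, 20, 40),
                               rng.uniform(-3, 3, 40),
                               rng.uniform(-3, 3, 40)])
        got = interpolate_velocity(grid, u, pts)
        expect = b + pts @ a * 1e-5
        for c in range(3):
            np.testing.assert_allclose(got[:, c], expect, atol=1e-10)

    def test_kernel_moments(self):
        r = np.linspace(-0.49, 0.49, 11)
        for rr in r:
            shifts = np.arange(-3, 4) + rr
            w = peskin4(shifts)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert (w * shifts).sum() == pytest.approx(0.0, abs=1e-12)


class TestViscosityField:
    def test_no_cells_uniform_plasma(self, tube_geometry):
        _, _, _, grid = tube_geometry
        mu = viscosity_field(grid, [])
        assert np.all(mu == 0.001)

    def test_sphere_cell_volume_from_indicator(self, tube_geometry):
        _, _, _, grid = tube_geometry
        sph = make_biconcave(7.8, 3, sphere_path=True)
        verts = sph.vertices * 2.0 + np.array([12.0, 0, 0])  # radius 2 µm
        from redwall.solver import cell_indicator

        ind = cell_indicator(grid, [(verts, sph.triangles)])
        vol = ind.sum() * grid.h**3
        assert vol == pytest.approx(4 * np.pi / 3 * 8.0, rel=0.05)
        mu = viscosity_field(grid, [(verts, sph.triangles)])
        assert mu.max() == pytest.approx(0.005, rel=1e-6)
        assert mu[0, 0, 0] == 0.001  # far corner stays plasma

    def test_open_surface_rejected(self, tube_geometry):
        _, _, _, grid = tube_geometry
        sph = make_biconcave(7.8, 2, sphere_path=True)
        with pytest.raises(ValueError, match="open cell surface"):
            viscosity_field(grid, [(sph.vertices + np.array([12.0, 0, 0]),
                                    sph.triangles[:-3])])


class TestStokesStep:
    def test_rest_state_stays_at_rest(self, tube_geometry):
        _, _, _, grid = tube_geometry
        sol = StokesSolver(grid, BoundaryCondition("pressure_drop", 0.0))
        st = sol.initial_state()
        sol.step(st, 1e-5)
        for c in range(3):
            assert np.abs(st.u[c]).max() == 0.0

    def test_unknown_bc_kind_rejected(self):
        with pytest.raises(ValueError, match="boundary-condition"):
            BoundaryCondition("magic", 1.0)

    def test_divergence_free_after_projection(self, poiseuille_steady):
        sol, state = poiseuille_steady
        assert sol.last_divergence < 1e-8

    def test_poiseuille_centerline_velocity(self, poiseuille_steady,
                                            tube_geometry):
        _, _, _, grid = tube_geometry
        sol, state = poiseuille_steady
        pts = np.column_stack([np.linspace(2, 22, 11), np.zeros(11),
                               np.zeros(11)])
        u = interpolate_velocity(grid, state.u, pts)[:, 0].mean()
        exact = 0.1e6 * (5e-6) ** 2 / (4 * 0.001)
        assert u == pytest.approx(exact, rel=0.03)

    def test_steady_state_is_time_independent(self, poiseuille_steady):
        sol, state = poiseuille_steady
        before = [a.copy() for a in state.u]
        sol.step(state, 2e-5)
        num = np.sqrt(sum(((state.u[c] - before[c]) ** 2).sum()
                          for c in range(3)))
        den = np.sqrt(sum((before[c] ** 2).sum() for c in range(3)))
        # restore for other tests sharing the fixture
        for c in range(3):
            state.u[c][:] = before[c]
        assert num / den < 1e-8

    def test_transverse_velocity_vanishes_in_straight_tube(
            self, poiseuille_steady):
        _, state = poiseuille_steady
        umax = np.abs(state.u[0]).max()
        assert np.abs(state.u[1]).max() < 1e-12 * umax
        assert np.abs(state.u[2]).max() < 1e-12 * umax

    def test_mass_conservation_along_tube(self, poiseuille_steady,
                                          tube_geometry):
        _, _, _, grid = tube_geometry
        sol, state = poiseuille_steady
        rates = [sol.flow_rate(state.u, i) for i in range(grid.shape[0])]
        assert np.ptp(rates) / np.mean(rates) < 0.01

    def test_capped_tube_conserves_flux_exactly(self):
        """Inlet-driven capped run: the metered flux is identical at every
        cross-section (wall faces carry no mass flux by construction)."""
        mesh, _ = make_tube(8.0, 20.0, None, 0.5)
        df = signed_distance(mesh, 0.5, min_diameter=8.0)
        grid = classify_grid(df, 0.5, lo=np.array([-0.5, -5.0, -5.0]),
                             hi=np.array([20.5, 5.0, 5.0]), periodic_x=False)
        Q = 1.0e-13
        sol = StokesSolver(grid, BoundaryCondition("inlet_flow_rate", Q))
        sol.set_inlet_profile()
        st = sol.initial_state()
        for _ in range(60):
            sol.step(st, 2e-5)
        rates = [sol.flow_rate(st.u, i) for i in range(grid.shape[0] + 1)]
        assert rates[0] == pytest.approx(Q, rel=1e-12)
        assert np.ptp(rates) / Q < 1e-10

    def test_flow_rate_bc_reaches_target(self, tube_geometry):
        _, _, _, grid = tube_geometry
        Q = 2.0e-14
        sol = StokesSolver(grid, BoundaryCondition("inlet_flow_rate", Q))
        st = sol.run_to_steady(sol.initial_state(), 2e-5, tol=1e-9,
                               max_steps=1500)
        assert sol.flow_rate(st.u) == pytest.approx(Q, rel=0.01)


class TestStableDt:
    def test_plasma_limited_by_accuracy_cap(self, tube_geometry):
        _, _, _, grid = tube_geometry
        sol = StokesSolver(grid, BoundaryCondition("pressure_drop", 0.1))
        assert sol.stable_dt(has_cells=False) == pytest.approx(2.5e-5)

    def test_decreases_when_h_halves(self, tube_geometry):
        mesh, _, df, _ = tube_geometry
        half = 6.0
        lo = np.array([0.0, -half, -half])
        hi = np.array([24.0, half, half])
        dts = []
        for h in (1.0, 0.5):
            grid = classify_grid(df, h, lo=lo, hi=hi, periodic_x=True)
            sol = StokesSolver(grid, BoundaryCondition("pressure_drop", 0.1))
            dts.append(sol.stable_dt(has_cells=True))
        assert dts[1] < dts[0]


class TestGridConvergence:
    def test_poiseuille_observed_order(self):
        """Max-norm velocity error vs the parabola under grid refinement.

        The order is measured between the two finest grids (10 and 20 cells
        per radius); 5 cells per radius is outside the asymptotic range.
        """
        mesh, _ = make_tube(10.0, 8.0, None, 0.5)
        df = signed_distance(mesh, 0.4, min_diameter=10.0)
        G, R, mu = 0.1e6, 5e-6, 0.001
        errs = []
        hs = (0.5, 0.25)
        for h in hs:
            half = 6.0
            grid = classify_grid(df, h, lo=np.array([0.0, -half, -half]),
                                 hi=np.array([8.0, half, half]),
                                 periodic_x=True)
            sol = StokesSolver(grid, BoundaryCondition("pressure_drop", 0.1))
            st = sol.run_to_steady(sol.initial_state(), 4e-5, tol=1e-9,
                                   max_steps=2500)
            centers = grid.face_centers(0)
            r2 = (centers[..., 1] ** 2 + centers[..., 2] ** 2) * 1e-12
            exact = G * np.maximum(R**2 - r2, 0.0) / (4 * mu)
            mask = grid.face_fluid[0] & (r2 < (4.0e-6) ** 2)
            errs.append(np.abs(st.u[0] - exact)[mask].max())
        order = np.log(errs[0] / errs[1]) / np.log(hs[0] / hs[1])
        assert order >= 1.8
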