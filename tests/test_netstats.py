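"""Junction flux partitioning and network-level aggregation."""

import numpy as np
import pytest

from redwall.geometry import build_network, make_junction
from redwall.netstats import (BifurcationFlux, GatePlane, branch_fluxes,
                              gate_for_vessel, phase_separation_points,
                              phase_separation_vs_wss, vessel_table)
from redwall.wss import CallableSampler


def uniform_axial(speed=1e-3):
    return CallableSampler(
        lambda p: np.tile([speed, 0.0, 0.0], (len(np.atleast_2d(p)), 1)))


class TestGatePlane:
    def test_flux_of_uniform_flow_is_speed_times_area(self):
        g = GatePlane(0, np.array([10.0, 0, 0]), np.array([1.0, 0, 0]), 4.0)
        q = g.flux(uniform_axial(1e-3))
        assert q == pytest.approx(1e-3 / 1e-6 * np.pi * 16.0, rel=1e-6)

    def test_crossing_count_net_and_rate(self):
        g = GatePlane(0, np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), 5.0)
        t = np.linspace(0.0, 1.0, 11)
        # one cell crosses forward once, another wiggles back and forth
        c1 = np.linspace(-2, 2, 11)
        c2 = np.sin(2 * np.pi * t) * 3.0
        series = np.zeros((11, 2, 3))
        series[:, 0, 0] = c1
        series[:, 1, 0] = c2
        rate = g.count_crossings(series, t)
        assert rate == pytest.approx(1.0)

    def test_offside_cells_not_counted(self):
        g = GatePlane(0, np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), 2.0)
        t = np.linspace(0.0, 1.0, 5)
        series = np.zeros((5, 1, 3))
        series[:, 0, 0] = np.linspace(-1, 1, 5)
        series[:, 0, 1] = 10.0  # far outside the gate radius
        assert g.count_crossings(series, t) == 0.0


class TestBranchFluxes:
    @pytest.fixture(scope="class")
    def junction_spec(self):
        _, spec = make_junction("bifurcation", 12.0, (9.0, 9.0), (30.0, 30.0))
        return spec

    def test_symmetric_bifurcation_splits_evenly(self, junction_spec):
        # symmetric analytic field: radial-distance-shaped axial flow in
        # each branch; symmetry forces Q1* = 0.5
        spec = junction_spec

        rf = spec.vessel(0).radius
        # parabolic profiles with amplitudes chosen so the synthetic flow
        # conserves mass: each daughter carries half the feeder flux
        amp = {0: 1e-3, 1: 1e-3 * rf**2 / (2 * spec.vessel(1).radius ** 2),
               2: 1e-3 * rf**2 / (2 * spec.vessel(2).radius ** 2)}

        def field(pts):
            pts = np.atleast_2d(pts)
            u = np.zeros((len(pts), 3))
            for v in spec.vessels:
                a = v.centerline[0]
                t = v.centerline[-1] - a
                L = np.linalg.norm(t)
                t = t / L
                s = np.clip((pts - a) @ t, 0.0, L)
                d = np.linalg.norm(pts - a - s[:, None] * t[None], axis=1)
                w = np.maximum(1 - (d / v.radius) ** 2, 0.0)
                # confine each branch profile to its own segment interior
                w[(s <= 1e-9) | (s >= L - 1e-9)] = 0.0
                u += amp[v.id] * w[:, None] * t[None]
            return u

        fx = branch_fluxes(CallableSampler(field), spec)
        assert len(fx) == 1
        q1, q2 = fx[0].Q_star
        assert q1 == pytest.approx(0.5, abs=0.05)
        assert q1 + q2 == pytest.approx(1.0, rel=0.15)

    def test_flux_ratio_arithmetic(self):
        bf = BifurcationFlux(0, "bifurcation", 12.0, Q_F=10.0,
                             Q_D=(6.0, 4.0), N_F=10.0, N_D=(8.0, 2.0))
        n1, q1 = bf.N_star[0], bf.Q_star[0]
        assert n1 - q1 == pytest.approx(0.8 - 0.6)
        assert bf.phase_separation()[0] == pytest.approx(0.2)

    def test_simulated_junction_partitions_conservatively(self):
        """Plasma flow through a simulated bifurcation: gate-metered daughter
        fluxes sum to the feeder flux."""
        from redwall.geometry import signed_distance
        from redwall.solver import classify_grid
        from redwall.solver.simulation import SimulationConfig, run_simulation
        from redwall.wss import GridSampler

        mesh, spec = make_junction("bifurcation", 10.0, (8.0, 7.0),
                                   (32.0, 32.0), branch_length=20.0,
                                   mesh_size=1.0)
        df = signed_distance(mesh, 0.5, min_diameter=7.0)
        lo = mesh.vertices.min(axis=0) - 1.0
        hi = mesh.vertices.max(axis=0) + 1.0
        grid = classify_grid(df, 0.5, lo=lo, hi=hi, periodic_x=False)
        cfg = SimulationConfig(h=0.5, dt=2e-5, t_end=1.5e-3, sample_dt=5e-4,
                               bc_kind="inlet_flow_rate", bc_value=1.5e-13,
                               periodic_x=False, store_snapshots=False)
        res = run_simulation(grid, cfg)
        assert res.status == "ok"
        fx = branch_fluxes(GridSampler(grid, res.mean_u), spec)[0]
        q1, q2 = fx.Q_star
        # gate quadrature carries an O(h/R) staircase bias per gate at this
        # resolution; the partitioning ratios largely cancel it
        assert q1 + q2 == pytest.approx(1.0, abs=0.12)
        assert q1 > q2  # wider daughter carries more flow
        fx.check_conservation(rtol=0.15)

    def test_plasma_only_has_no_cell_flux(self, junction_spec):
        fx = branch_fluxes(uniform_axial(), junction_spec)
        assert fx[0].N_star is None

    def test_conservation_violation_detected(self):
        bf = BifurcationFlux(0, "bifurcation", 12.0, Q_F=10.0, Q_D=(6.0, 5.0))
        with pytest.raises(ValueError, match="mass conservation"):
            bf.check_conservation()


class TestPhaseSeparationRegression:
    def test_exact_line_recovered(self):
        fit = phase_separation_points([-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_proportional_partitioning_gives_zero_slope(self):
        spec = build_network(3, 1.6, 0.0, seed=0)
        bif = spec.bifurcations()
        fluxes = [BifurcationFlux(b.id, "bifurcation", 10.0, Q_F=10.0,
                                  Q_D=(q, 10 - q), N_F=20.0,
                                  N_D=(2 * q, 2 * (10 - q)))
                  for b, q in zip(bif, (6.0, 7.0, 8.0))]
        # N* = Q* at every bifurcation: all y = 0 regardless of the WSS x
        wss = {v.id: float(v.id**2) for v in spec.vessels}
        fit = phase_separation_vs_wss(fluxes, wss, spec)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_x_variance_flagged(self):
        fit = phase_separation_points([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        assert fit.degenerate

    def test_too_few_bifurcations_rejected(self):
        spec = build_network(2, 1.6, 0.0, seed=0)
        with pytest.raises(ValueError, match=">= 3"):
            phase_separation_vs_wss([], {}, spec)


class TestVesselTable:
    def test_records_match_network_and_self_pair_ratio_one(self):
        from redwall.geometry import make_tube
        from redwall.wss.fields import WSSField

        mesh, spec = make_tube(10.0, 30.0, None, 0.5)
        n = mesh.n_vertices
        tau = np.linspace(1, 2, n)
        f = WSSField(t_s=tau, t_theta=np.zeros(n), t_r_visc=np.zeros(n))
        df = vessel_table(spec, mesh, wss_rbc=f, wss_pl=f)
        assert list(df["vessel_id"]) == [v.id for v in spec.vessels]
        assert df["tau_ratio"].iloc[0] == pytest.approx(1.0)
        assert bool(df["paired"].iloc[0])

    def test_painted_fields_reproduce_roi_means(self):
        from redwall.geometry import make_junction
        from redwall.wss import roi_average
        from redwall.wss.fields import WSSField

        mesh, spec = make_junction("bifurcation", 12.0, (9.0, 8.0),
                                   (30.0, 30.0))
        n = mesh.n_vertices
        tau = np.zeros(n)
        paint = {0: 2.0, 1: 5.0, 2: 7.0}
        for vid, val in paint.items():
            tau[mesh.roi_labels == f"vessel:{vid}"] = val
        f = WSSField(t_s=tau, t_theta=np.zeros(n), t_r_visc=np.zeros(n))
        df = vessel_table(spec, mesh, wss_rbc=f)
        for vid, val in paint.items():
            row = df[df.vessel_id == vid].iloc[0]
            assert row.tau_rbc == pytest.approx(val)
            assert row.tau_rbc == pytest.approx(
                roi_average(f, mesh, f"vessel:{vid}"))
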