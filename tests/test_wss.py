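"""WSS/WSSG pipeline: frames, tractions, surface gradients, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from redwall.geometry import make_tube
from redwall.wss import (CallableSampler, GridSampler, cross_section_profiles,
                         local_frames, ratio_map, roi_average, temporal_rms,
                         time_average, vessel_std, wall_shear_stress, wssg)
from redwall.wss.fields import WSSField


@pytest.fixture(scope="module")
def tube_mesh():
    mesh, _ = make_tube(10.0, 24.0, None, 0.5)
    return mesh


def poiseuille_sampler(G=0.1e6, R=5e-6, mu=1e-3):
    def fn(pts):
        pts = np.atleast_2d(pts)
        r2 = (pts[:, 1] ** 2 + pts[:, 2] ** 2) * 1e-12
        u = np.zeros((len(pts), 3))
        u[:, 0] = G * np.maximum(R**2 - r2, 0.0) / (4 * mu)
        return u

    return CallableSampler(fn)


class TestLocalFrames:
    def test_axial_streamwise_direction_in_tube(self, tube_mesh):
        fr = local_frames(tube_mesh, poiseuille_sampler())
        lat = tube_mesh.roi_labels != "cap"
        assert np.abs(fr.e_s[lat] - [1.0, 0, 0]).max() < 1e-6
        fr.check_orthonormal()

    def test_swirl_field_gives_azimuthal_streamwise(self, tube_mesh):
        def swirl(pts):
            pts = np.atleast_2d(pts)
            u = np.zeros((len(pts), 3))
            u[:, 1] = -pts[:, 2] * 1e-4
            u[:, 2] = pts[:, 1] * 1e-4
            return u

        fr = local_frames(tube_mesh, CallableSampler(swirl))
        lat = tube_mesh.roi_labels != "cap"
        assert np.abs(fr.e_s[lat] @ np.array([1.0, 0, 0])).max() < 1e-6

    def test_stagnation_vertices_flagged_with_fallback(self, tube_mesh):
        zero = CallableSampler(
            lambda p: np.zeros((len(np.atleast_2d(p)), 3)))
        fr = local_frames(tube_mesh, zero)
        assert fr.stagnant.all()
        fr.check_orthonormal()


class TestWallShearStress:
    def test_poiseuille_tau_closed_form(self, tube_mesh):
        fr = local_frames(tube_mesh, poiseuille_sampler())
        w = wall_shear_stress(poiseuille_sampler(), tube_mesh, fr, 0.3, 0.001)
        lat = tube_mesh.roi_labels != "cap"
        # tau = G R / 2 = 0.25 Pa = 2.5 dyne/cm²
        assert w.t_s[lat].mean() == pytest.approx(2.5, rel=0.05)

    def test_uniform_field_zero_stress(self, tube_mesh):
        uni = CallableSampler(
            lambda p: np.tile([3e-4, 0, 0], (len(np.atleast_2d(p)), 1)))
        fr = local_frames(tube_mesh, uni)
        w = wall_shear_stress(uni, tube_mesh, fr, 0.3, 0.001)
        assert np.abs(w.t_s).max() < 1e-12

    def test_span_above_cfl_bound_rejected(self, tube_mesh):
        fr = local_frames(tube_mesh, poiseuille_sampler())
        with pytest.raises(ValueError, match="cell-free"):
            wall_shear_stress(poiseuille_sampler(), tube_mesh, fr, 0.5)

    def test_traction_hierarchy_on_analytic_tube(self, tube_mesh):
        fr = local_frames(tube_mesh, poiseuille_sampler())
        w = wall_shear_stress(poiseuille_sampler(), tube_mesh, fr, 0.3, 0.001)
        lat = tube_mesh.roi_labels != "cap"
        assert np.abs(w.t_theta[lat]).max() <= 1e-4 * np.abs(w.t_s[lat]).max()
        assert np.abs(w.t_r_visc[lat]).max() <= 1e-4 * np.abs(w.t_s[lat]).max()


class TestWSSG:
    def test_linear_tau_gradient_exact(self, tube_mesh):
        fr = local_frames(tube_mesh, poiseuille_sampler())
        k = 3.0
        n = tube_mesh.n_vertices
        wf = WSSField(t_s=k * tube_mesh.vertices[:, 0],
                      t_theta=np.zeros(n), t_r_visc=np.zeros(n))
        g = wssg(wf, tube_mesh, fr, 0.3)
        ok = (tube_mesh.roi_labels != "cap") & g.valid
        assert np.abs(g.grad_s[ok] - k).max() < 1e-6
        assert np.abs(g.grad_theta[ok]).max() < 1e-6

    def test_constant_tau_zero_gradient(self, tube_mesh):
        fr = local_frames(tube_mesh, poiseuille_sampler())
        n = tube_mesh.n_vertices
        wf = WSSField(t_s=np.full(n, 4.2), t_theta=np.zeros(n),
                      t_r_visc=np.zeros(n))
        g = wssg(wf, tube_mesh, fr, 0.3)
        assert np.abs(g.grad_s).max() < 1e-10
        assert np.abs(g.grad_theta).max() < 1e-10

    def test_sin_theta_surface_gradient(self, tube_mesh):
        fr = local_frames(tube_mesh, poiseuille_sampler())
        th = np.arctan2(tube_mesh.vertices[:, 2], tube_mesh.vertices[:, 1])
        n = tube_mesh.n_vertices
        wf = WSSField(t_s=np.sin(th), t_theta=np.zeros(n),
                      t_r_visc=np.zeros(n))
        g = wssg(wf, tube_mesh, fr, 0.3)
        ok = (tube_mesh.roi_labels != "cap") & g.valid
        exact = np.cos(th) / 5.0
        assert np.abs(g.grad_theta[ok] - exact[ok]).max() < (0.3 / 5.0) ** 2 + 1e-9

    def test_magnitude_dominates_components(self, tube_mesh):
        fr = local_frames(tube_mesh, poiseuille_sampler())
        rng = np.random.default_rng(0)
        n = tube_mesh.n_vertices
        wf = WSSField(t_s=rng.normal(size=n), t_theta=np.zeros(n),
                      t_r_visc=np.zeros(n))
        g = wssg(wf, tube_mesh, fr, 0.3)
        assert np.all(g.magnitude >= np.abs(g.grad_s) - 1e-14)
        assert np.all(g.magnitude >= np.abs(g.grad_theta) - 1e-14)


class TestTimeAverage:
    def test_steady_series_unchanged(self, tube_geometry):
        _, _, _, grid = tube_geometry
        u = [np.random.default_rng(0).normal(size=grid.face_shape(c))
             for c in range(3)]
        avg = time_average([u, u, u])
        for c in range(3):
            np.testing.assert_allclose(avg[c], u[c], rtol=0, atol=1e-15)

    def test_opposite_samples_cancel(self, tube_geometry):
        _, _, _, grid = tube_geometry
        u = [np.ones(grid.face_shape(c)) for c in range(3)]
        mu = [-a for a in u]
        avg = time_average([u, mu])
        for c in range(3):
            assert np.abs(avg[c]).max() == 0.0

    def test_sinusoid_over_whole_periods(self):
        shape = ((4, 3, 3), (4, 4, 3), (4, 3, 4))
        times = np.arange(32) / 32.0
        series = []
        for t in times:
            series.append([5.0 + 2.0 * np.sin(2 * np.pi * 2 * t)
                           * np.ones(s) for s in shape])
        avg = time_average(series, times=list(times))
        for c in range(3):
            np.testing.assert_allclose(avg[c], 5.0, atol=1e-10)

    def test_nonuniform_cadence_rejected(self):
        u = [np.zeros((3, 3, 3))] * 3
        with pytest.raises(ValueError, match="uniform"):
            time_average([u, u, u], times=[0.0, 1.0, 3.0])


class TestStatistics:
    def test_roi_average_hand_quadrature(self):
        from redwall.fixtures import _two_patch_mesh

        toy = _two_patch_mesh()
        tau = np.array([2.0, 2.0, 2.0, 6.0, 6.0, 6.0])
        assert roi_average(tau, toy, "vessel:0") == pytest.approx(5.0)

    def test_roi_average_constant(self, tube_mesh):
        c = 3.7
        vals = np.full(tube_mesh.n_vertices, c)
        assert roi_average(vals, tube_mesh, "vessel:0") == pytest.approx(c)

    def test_empty_roi_errors(self, tube_mesh):
        with pytest.raises(ValueError, match="no valid vertices"):
            roi_average(np.ones(tube_mesh.n_vertices), tube_mesh, "vessel:99")

    def test_vessel_std_printed_formula(self):
        from redwall.fixtures import _two_patch_mesh

        toy = _two_patch_mesh()
        vals = np.array([1.0, 3.0, 0, 0, 0, 0])
        mask = np.array([True, True, False, False, False, False])
        assert vessel_std(vals, toy, mask) == pytest.approx(np.sqrt(2) / 2)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_vessel_std_scale_invariant(self, scale):
        from redwall.fixtures import _two_patch_mesh

        toy = _two_patch_mesh()
        vals = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 11.0])
        base = vessel_std(vals, toy, "vessel:0")
        assert vessel_std(scale * vals, toy, "vessel:0") == pytest.approx(
            base, rel=1e-12)

    def test_temporal_rms_sinusoid(self):
        from redwall.fixtures import _two_patch_mesh

        toy = _two_patch_mesh()
        m, a = 2.0, 0.6
        t = np.arange(256) / 256.0
        series = [np.full(6, m + a * np.sin(2 * np.pi * 4 * tk)) for tk in t]
        r = temporal_rms(series, toy, "vessel:0")
        assert r.absolute == pytest.approx(a / np.sqrt(2), rel=1e-4)
        assert r.relative == pytest.approx(a / (np.sqrt(2) * m), rel=1e-4)
        # doubling the amplitude doubles the absolute RMS
        series2 = [np.full(6, m + 2 * a * np.sin(2 * np.pi * 4 * tk))
                   for tk in t]
        r2 = temporal_rms(series2, toy, "vessel:0")
        assert r2.absolute == pytest.approx(2 * r.absolute, rel=1e-6)

    def test_temporal_rms_constant_signal_zero(self):
        from redwall.fixtures import _two_patch_mesh

        toy = _two_patch_mesh()
        series = [np.full(6, 3.3)] * 10
        r = temporal_rms(series, toy, "vessel:0")
        assert r.absolute == 0.0
        assert r.relative == 0.0


class TestRatioMap:
    def _field(self, vals, bc="inlet_flow_rate"):
        n = len(vals)
        return WSSField(t_s=np.asarray(vals, float), t_theta=np.zeros(n),
                        t_r_visc=np.zeros(n), bc_kind=bc)

    def test_identical_fields_ratio_one(self, tube_mesh):
        f = self._field(np.linspace(1, 2, tube_mesh.n_vertices))
        pw, roi = ratio_map(f, f, tube_mesh)
        ok = np.isfinite(pw)
        assert np.allclose(pw[ok], 1.0)
        assert roi["vessel:0"] == pytest.approx(1.0, abs=1e-10)

    def test_proportional_fields(self, tube_mesh):
        base = np.linspace(1, 2, tube_mesh.n_vertices)
        pw, roi = ratio_map(self._field(3 * base), self._field(base),
                            tube_mesh)
        assert roi["vessel:0"] == pytest.approx(3.0, rel=1e-10)

    def test_pressure_bc_pair_refused(self, tube_mesh):
        f1 = self._field(np.ones(tube_mesh.n_vertices), bc="pressure_drop")
        f2 = self._field(np.ones(tube_mesh.n_vertices))
        with pytest.raises(ValueError, match="inlet-flow-rate"):
            ratio_map(f1, f2, tube_mesh)


class TestProfiles:
    def test_poiseuille_bluntness_is_two(self, tube_mesh):
        prof = cross_section_profiles(
            poiseuille_sampler(), tube_mesh.distance_fn,
            np.array([12.0, 0, 0]), np.array([1.0, 0, 0]),
            np.array([0.0, 1, 0]))
        assert prof.bluntness == pytest.approx(2.0, rel=0.03)
        assert prof.skew_side == "none"

    def test_plug_profile_bluntness_one(self, tube_mesh):
        def plug(pts):
            pts = np.atleast_2d(pts)
            r = np.linalg.norm(pts[:, 1:], axis=1)
            u = np.zeros((len(pts), 3))
            u[:, 0] = np.where(r < 5.0, 1e-3, 0.0)
            return u

        prof = cross_section_profiles(
            CallableSampler(plug), tube_mesh.distance_fn,
            np.array([12.0, 0, 0]), np.array([1.0, 0, 0]),
            np.array([0.0, 1, 0]))
        assert prof.bluntness == pytest.approx(1.0, rel=0.02)

    def test_chord_outside_lumen_rejected(self, tube_mesh):
        with pytest.raises(ValueError, match="does not intersect"):
            cross_section_profiles(
                poiseuille_sampler(), tube_mesh.distance_fn,
                np.array([12.0, 20.0, 0]), np.array([1.0, 0, 0]),
                np.array([0.0, 0, 1]), search_half_length=3.0)


class TestPipelineSelfConsistency:
    def test_average_then_stress_commutes_on_steady_field(
            self, tube_geometry, poiseuille_steady):
        mesh, _, _, grid = tube_geometry
        _, state = poiseuille_steady
        series = [[a.copy() for a in state.u] for _ in range(4)]
        avg = time_average(series)
        s_avg = GridSampler(grid, avg)
        s_one = GridSampler(grid, state.u)
        fr = local_frames(mesh, s_one)
        w1 = wall_shear_stress(s_avg, mesh, fr, 0.3)
        w2 = wall_shear_stress(s_one, mesh, fr, 0.3)
        np.testing.assert_allclose(w1.t_s, w2.t_s, rtol=1e-12, atol=1e-14)
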