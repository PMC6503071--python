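"""RBC membrane mechanics: resting geometry, elastic and bending forces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from redwall.geometry.sdf import DistanceField, straight_tube_distance
from redwall.membrane import (area_volume, bending_energy, bending_forces,
                              make_biconcave, membrane_forces, seed_cells,
                              skalak_energy, skalak_forces)


@pytest.fixture(scope="module")
def cell3():
    return make_biconcave(7.8, 3)


class TestBiconcaveGeometry:
    def test_canonical_area_and_volume(self):
        cell = make_biconcave(7.8, 5)
        assert cell.reference_area == pytest.approx(134.1, rel=0.01)
        assert cell.reference_volume == pytest.approx(94.1, rel=0.01)

    def test_end_to_end_extent(self):
        cell = make_biconcave(7.8, 4)
        extent = 2 * np.hypot(cell.vertices[:, 0], cell.vertices[:, 1]).max()
        assert extent == pytest.approx(7.8, rel=0.005)

    def test_sphere_path_closed_forms(self):
        sph = make_biconcave(7.8, 4, sphere_path=True)
        assert sph.reference_area == pytest.approx(4 * np.pi, rel=0.005)
        assert sph.reference_volume == pytest.approx(4 * np.pi / 3, rel=0.005)

    def test_refinement_precondition(self):
        with pytest.raises(ValueError, match="n_refine"):
            make_biconcave(7.8, 1)


class TestAreaVolume:
    def test_translation_invariance(self, cell3):
        a0, v0 = area_volume(cell3.vertices, cell3.triangles)
        a1, v1 = area_volume(cell3.vertices + np.array([13.0, -7.0, 4.0]),
                             cell3.triangles)
        assert v1 == pytest.approx(v0, rel=1e-12)
        assert a1 == pytest.approx(a0, rel=1e-12)

    def test_inconsistent_orientation_rejected(self, cell3):
        tris = cell3.triangles.copy()
        tris[0] = tris[0, ::-1]
        with pytest.raises(ValueError, match="orientation"):
            area_volume(cell3.vertices, tris)


class TestSkalak:
    def test_zero_force_at_reference(self, cell3):
        f = skalak_forces(cell3, cell3.vertices).elastic
        scale = cell3.G_s * cell3.reference_area * 1e-12 / 1e-6
        assert np.abs(f).max() < 1e-12 * scale

    def test_frame_invariance_under_rotation(self, cell3):
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        f = skalak_forces(cell3, cell3.vertices @ R.T).elastic
        scale = cell3.G_s * cell3.reference_area * 1e-12 / 1e-6
        assert np.abs(f).max() < 1e-10 * scale

    def test_degenerate_triangle_rejected(self, cell3):
        x = cell3.vertices.copy()
        tri0 = cell3.triangles[0]
        x[tri0[1]] = x[tri0[0]]
        x[tri0[2]] = x[tri0[0]]
        with pytest.raises(ValueError, match="triangle"):
            skalak_forces(cell3, x)

    def test_energy_nonnegative_and_zero_at_reference(self, cell3):
        assert skalak_energy(cell3, cell3.vertices) == pytest.approx(0.0,
                                                                     abs=1e-25)
        rng = np.random.default_rng(3)
        x = cell3.vertices + 0.05 * rng.normal(size=cell3.vertices.shape)
        assert skalak_energy(cell3, x) > 0


class TestBending:
    def test_sphere_willmore_energy(self):
        sph = make_biconcave(7.8, 5, sphere_path=True)
        e = bending_energy(sph, sph.vertices)
        assert e == pytest.approx(8 * np.pi * sph.k_b, rel=0.05)

    def test_sphere_forces_vanish_under_refinement(self):
        # uniform curvature: nodal forces are pure discretization error and
        # must converge away (RMS; the 12 valence-5 vertices carry an O(1)
        # pointwise curvature error intrinsic to cotangent operators)
        rms = {}
        for n in (3, 4, 5):
            sph = make_biconcave(7.8, n, sphere_path=True)
            f = bending_forces(sph, sph.vertices).bending
            rms[n] = float(np.sqrt((f**2).sum(axis=1).mean()))
        assert rms[5] < rms[4] < rms[3]
        assert rms[5] < 0.30 * rms[3]
        # flattening produces a genuine restoring force above the noise
        sph5 = make_biconcave(7.8, 5, sphere_path=True)
        squashed = sph5.vertices * np.array([1.0, 1.0, 0.5])
        fsq = bending_forces(sph5, squashed).bending
        assert np.sqrt((fsq**2).sum(axis=1).mean()) > rms[5]

    def test_energy_scale_invariance(self):
        # Willmore energy of a sphere is radius independent
        sph = make_biconcave(7.8, 4, sphere_path=True)
        e1 = bending_energy(sph, sph.vertices)
        e2 = bending_energy(sph, 2.0 * sph.vertices)
        assert e2 == pytest.approx(e1, rel=1e-12)

    def test_energy_zero_at_matched_spontaneous_curvature(self):
        sph = make_biconcave(7.8, 4, sphere_path=True)
        sph.c0 = 2.0  # 1/µm, = 2/R for the unit-radius sphere
        e_matched = bending_energy(sph, sph.vertices)
        sph.c0 = 0.0
        e_helfrich = bending_energy(sph, sph.vertices)
        assert e_matched < 1e-3 * e_helfrich


class TestForceGradientConsistency:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=5, deadline=None)
    def test_forces_are_negative_energy_gradients(self, seed):
        cell = make_biconcave(7.8, 2)
        rng = np.random.default_rng(seed)
        x = cell.vertices * 1.04 + 0.03 * rng.normal(size=cell.vertices.shape)
        fe = skalak_forces(cell, x).elastic
        fb = bending_forces(cell, x).bending
        eps = 1e-7
        idx = rng.integers(0, cell.n_vertices, 3)
        for v in idx:
            for ax in range(3):
                xp = x.copy(); xp[v, ax] += eps
                xm = x.copy(); xm[v, ax] -= eps
                ge = -(skalak_energy(cell, xp) - skalak_energy(cell, xm)) \
                    / (2 * eps * 1e-6)
                gb = -(bending_energy(cell, xp) - bending_energy(cell, xm)) \
                    / (2 * eps * 1e-6)
                assert ge == pytest.approx(fe[v, ax], rel=1e-5,
                                           abs=1e-5 * np.abs(fe).max())
                assert gb == pytest.approx(fb[v, ax], rel=1e-5,
                                           abs=1e-5 * np.abs(fb).max())

    def test_zero_net_force_and_torque(self, cell3):
        rng = np.random.default_rng(11)
        x = cell3.vertices * 1.05 + 0.05 * rng.normal(
            size=cell3.vertices.shape)
        fd = membrane_forces(cell3, x)
        fd.check_balance(x)


class TestSeeding:
    @pytest.fixture(scope="class")
    def tube_df(self):
        fn = straight_tube_distance(5.0)
        xs = np.arange(0, 24.5, 0.5)
        ys = np.arange(-6, 6.5, 0.5)
        vals = fn(np.stack(np.meshgrid(xs, ys, ys, indexing="ij"),
                           axis=-1).reshape(-1, 3)).reshape(49, 25, 25)
        return DistanceField(origin=np.array([0.0, -6, -6]), h=0.5,
                             values=vals, fn=fn)

    def test_count_follows_hematocrit_arithmetic(self, tube_df, cell3):
        from redwall.membrane.seeding import lumen_volume

        V = lumen_volume(tube_df)
        ht = 0.1
        n_expect = round(ht * V / cell3.reference_volume)
        pl = seed_cells(tube_df, ht, seed=4, cell=cell3)
        assert len(pl) == n_expect

    def test_zero_hematocrit_empty(self, tube_df):
        assert seed_cells(tube_df, 0.0, seed=1) == []

    def test_deterministic_for_fixed_seed(self, tube_df, cell3):
        a = seed_cells(tube_df, 0.1, seed=9, cell=cell3)
        b = seed_cells(tube_df, 0.1, seed=9, cell=cell3)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.position, pb.position)
            np.testing.assert_array_equal(pa.rotation, pb.rotation)

    def test_no_wall_penetration_and_no_overlap(self, tube_df, cell3):
        from scipy.spatial import cKDTree

        pl = seed_cells(tube_df, 0.15, seed=5, cell=cell3)
        assert len(pl) >= 2
        clouds = [p.apply(cell3) for p in pl]
        for v in clouds:
            assert tube_df.sample(v).max() < -0.1
        for i in range(len(clouds)):
            for j in range(i + 1, len(clouds)):
                d, _ = cKDTree(clouds[i]).query(clouds[j], k=1)
                assert d.min() > 0.1
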