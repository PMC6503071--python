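"""Synthetic geometry: tubes, junctions, networks, signed distance."""

import numpy as np
import pytest

from redwall.geometry import (DIAMETER_BOUNDS, build_network, make_junction,
                              make_tube, polyline_arc_length, signed_distance,
                              sinusoidal_bend)
from redwall.geometry.wallmesh import CAP_LABEL


class TestTube:
    def test_lateral_area_matches_cylinder(self):
        mesh, _ = make_tube(10.0, 50.0, None, 0.5)
        assert mesh.total_area() == pytest.approx(np.pi * 10 * 50, rel=0.01)

    def test_vertices_at_exact_radius(self):
        mesh, _ = make_tube(10.0, 50.0, None, 0.5)
        r = np.linalg.norm(mesh.vertices[:, 1:], axis=1)
        assert np.max(np.abs(r - 5.0)) / 5.0 < 0.005

    def test_curved_centerline_longer_than_chord(self):
        # independent polyline quadrature of the arc length
        _, spec = make_tube(8.0, 60.0, sinusoidal_bend(6.0), 0.4)
        cl = spec.vessels[0].centerline
        arc_oracle = float(np.sum(np.sqrt(
            np.sum(np.diff(cl, axis=0) ** 2, axis=1))))
        assert arc_oracle > 60.0
        assert polyline_arc_length(cl) == pytest.approx(arc_oracle, rel=1e-12)

    def test_coarse_mesh_rejected_with_named_constraint(self):
        with pytest.raises(ValueError, match="diameter/6"):
            make_tube(6.0, 30.0, None, 1.5)

    def test_watertight_and_labeled(self):
        mesh, _ = make_tube(10.0, 30.0, None, 0.5)
        mesh.validate()
        lateral = mesh.roi_labels != CAP_LABEL
        assert set(mesh.roi_labels[lateral]) == {"vessel:0"}
        assert len(mesh.boundary_loops()) == 2


class TestJunction:
    @pytest.mark.parametrize("kind,feeder,branches,angles", [
        ("bifurcation", 14.0, (10.0, 8.0), (35.0, 35.0)),
        ("convergence", 11.0, (6.0, 11.0), (30.0, 20.0)),
    ])
    def test_three_caps_and_sphere_topology(self, kind, feeder, branches,
                                            angles):
        mesh, spec = make_junction(kind, feeder, branches, angles)
        assert len(mesh.boundary_loops()) == 3
        assert mesh.euler_characteristic_capped() == 2
        mesh.validate()
        assert len(spec.vessels) == 3

    def test_roi_labels_count_four_excluding_caps(self):
        # Horton-ratio daughters: both = feeder / r
        r = 1.6
        feeder = 12.8
        mesh, _ = make_junction("bifurcation", feeder,
                                (feeder / r, feeder / r), (32.0, 32.0))
        labels = {str(l) for l in mesh.roi_labels} - {CAP_LABEL}
        assert len(labels) == 4
        assert "bifurcation:0" in labels

    def test_wider_daughters_rejected(self):
        with pytest.raises(ValueError, match="wider than the feeder"):
            make_junction("bifurcation", 8.0, (10.0, 6.0), (35.0, 35.0))

    def test_extreme_angles_rejected(self):
        with pytest.raises(ValueError, match="self-intersecting"):
            make_junction("bifurcation", 12.0, (9.0, 9.0), (4.0, 4.0))


class TestNetwork:
    def test_diameters_within_morphometric_bounds(self):
        spec = build_network(3, 1.6, 0.3, seed=1)
        for v in spec.vessels:
            assert DIAMETER_BOUNDS[0] <= v.diameter <= DIAMETER_BOUNDS[1]

    def test_deterministic_for_fixed_seed(self):
        a = build_network(2, 1.5, 0.0, seed=7)
        b = build_network(2, 1.5, 0.0, seed=7)
        for va, vb in zip(a.vessels, b.vessels):
            np.testing.assert_array_equal(va.centerline, vb.centerline)

    def test_bifurcations_equal_convergences(self):
        spec = build_network(3, 1.6, 0.3, seed=1)
        assert len(spec.bifurcations()) == len(spec.convergences())
        assert len(spec.bifurcations()) > 0

    def test_graph_connected_and_serializable(self):
        spec = build_network(3, 1.6, 0.3, seed=3)
        spec.validate()
        rt = type(spec).from_json(spec.to_json())
        assert [v.id for v in rt.vessels] == [v.id for v in spec.vessels]

    def test_bad_horton_ratio_rejected(self):
        with pytest.raises(ValueError, match="diameter bound"):
            build_network(3, 2.1, 0.3, seed=0)


class TestSignedDistance:
    def test_axis_and_wall_values_on_tube(self):
        mesh, _ = make_tube(10.0, 30.0, None, 0.5)
        df = signed_distance(mesh, 0.5, min_diameter=10.0)
        assert df.sample(np.array([[15.0, 0, 0]]))[0] == pytest.approx(-5.0,
                                                                       abs=0.5)
        on_wall = df.sample(np.array([[15.0, 5.0, 0.0]]))[0]
        assert abs(on_wall) <= 0.25

    def test_coarse_h_rejected(self):
        mesh, _ = make_tube(10.0, 30.0, None, 0.5)
        with pytest.raises(ValueError, match="too coarse"):
            signed_distance(mesh, 2.0, min_diameter=10.0)

    def test_eikonal_property_off_medial_axis(self):
        mesh, _ = make_tube(10.0, 30.0, None, 0.5)
        df = signed_distance(mesh, 0.5, min_diameter=10.0)
        rng = np.random.default_rng(0)
        r = rng.uniform(2.0, 7.0, 200)
        th = rng.uniform(0, 2 * np.pi, 200)
        pts = np.column_stack([rng.uniform(5, 25, 200), r * np.cos(th),
                               r * np.sin(th)])
        g = np.linalg.norm(df.gradient(pts), axis=1)
        assert np.max(np.abs(g - 1.0)) < 0.05

    def test_matches_brute_force_nearest_triangle(self):
        import trimesh

        mesh, _ = make_tube(8.0, 20.0, None, 0.6)
        h = 0.5
        df = signed_distance(mesh, h, min_diameter=8.0)
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.uniform(2, 18, 1000),
                               rng.uniform(-3.5, 3.5, 1000),
                               rng.uniform(-3.5, 3.5, 1000)])
        # brute force: distance to every triangle, all points
        tri = mesh.vertices[mesh.triangles]
        best = np.full(len(pts), np.inf)
        for t in range(len(tri)):
            cp = trimesh.triangles.closest_point(
                np.broadcast_to(tri[t], (len(pts), 3, 3)), pts)
            best = np.minimum(best, np.linalg.norm(pts - cp, axis=1))
        inside = np.linalg.norm(pts[:, 1:], axis=1) < 4.0
        oracle = np.where(inside, -best, best)
        err = np.abs(df.sample(pts) - oracle)
        assert err.max() <= h
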