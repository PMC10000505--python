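"""Bolus geometry: ellipsoid fit, frames, grid spreading, patches,
clearances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helmetplan as hp
from helmetplan.geometry import (ANTENNA_RADIUS_MM, antenna_frame,
                                 clearance_constraints, locate_patch,
                                 uniform_surface_sample)


def _sample_on_ellipsoid(radii, n, rng):
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * np.asarray(radii)


class TestEllipsoidFit:
    def test_recovers_study_radii_from_exact_points(self):
        rng = np.random.default_rng(0)
        pts = _sample_on_ellipsoid((125.0, 142.0, 144.0), 300, rng)
        e, resid = hp.fit_bolus_ellipsoid(pts)
        assert np.allclose(e.radii, (125.0, 142.0, 144.0), rtol=0.01)
        assert resid < 1e-9

    def test_sphere_symmetry(self):
        rng = np.random.default_rng(1)
        pts = _sample_on_ellipsoid((80.0, 80.0, 80.0), 200, rng)
        e, _ = hp.fit_bolus_ellipsoid(pts)
        assert np.allclose(e.radii, 80.0, rtol=1e-6)

    def test_noisy_sphere_recovery(self):
        rng = np.random.default_rng(42)
        pts = _sample_on_ellipsoid((80.0, 80.0, 80.0), 500, rng)
        pts += rng.normal(0.0, 1.0, pts.shape)  # 1 mm noise
        e, _ = hp.fit_bolus_ellipsoid(pts)
        assert np.allclose(e.radii, 80.0, rtol=0.02)

    def test_offset_moves_surface_outward(self):
        rng = np.random.default_rng(2)
        pts = _sample_on_ellipsoid((75.0, 92.0, 94.0), 400, rng)
        e, _ = hp.fit_bolus_ellipsoid(pts, offset=50.0)
        assert np.all(e.radii > (75.0, 92.0, 94.0))
        assert np.allclose(e.radii, (125.0, 142.0, 144.0), atol=6.0)

    def test_degenerate_cloud_rejected(self):
        pts = np.zeros((20, 3))
        pts[:, 0] = np.arange(20)  # collinear
        with pytest.raises(ValueError):
            hp.fit_bolus_ellipsoid(pts)


class TestAntennaFrame:
    def test_pole_on_sphere(self):
        e = hp.Ellipsoid(radii=(100.0, 100.0, 100.0))
        pose = antenna_frame(e, 0.0, 0.0, retract=False)
        assert np.allclose(pose.surface_point, (0, 0, 100.0))
        assert np.allclose(pose.W, (0, 0, -1.0))

    def test_equator_point_on_study_ellipsoid(self, study_ellipsoid):
        pose = antenna_frame(study_ellipsoid, np.pi / 2, 0.0, retract=False)
        assert np.allclose(pose.surface_point, (125.0, 0.0, 0.0), atol=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(theta=st.floats(0.01, 2.1), phi=st.floats(0.0, 2 * np.pi))
    def test_frame_orthonormal_right_handed(self, theta, phi):
        e = hp.Ellipsoid(radii=(125.0, 142.0, 144.0), trim_offset=77.0)
        pose = antenna_frame(e, theta, phi, retract=False)
        F = pose.frame
        assert np.allclose(F @ F.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(F) == pytest.approx(1.0, abs=1e-10)
        # U tangent: orthogonal to the surface normal, and in the ZW plane
        assert abs(np.dot(pose.U, pose.W)) < 1e-10
        assert abs(np.dot(pose.V, [0, 0, 1])) < 1e-10

    def test_w_points_inward(self, study_ellipsoid):
        pose = antenna_frame(study_ellipsoid, 1.0, 2.0, retract=False)
        inner = pose.surface_point + 5.0 * pose.W
        assert study_ellipsoid.level(inner) < 0

    def test_retraction_keeps_back_plate_in_water(self, study_ellipsoid):
        pose = antenna_frame(study_ellipsoid, 1.3, 0.7)
        assert pose.retraction > 0
        hu, hv = 87.0 / 2, 62.0 / 2
        for su in (-1, 1):
            for sv in (-1, 1):
                corner = pose.O + su * hu * pose.U + sv * hv * pose.V
                assert study_ellipsoid.level(corner) <= 1e-9

    def test_phase_center_offset(self, study_ellipsoid):
        pose = antenna_frame(study_ellipsoid, 1.0, 0.0)
        assert np.allclose(pose.phase_center - pose.O, 14.0 * pose.W)

    def test_trimmed_region_rejected(self, study_ellipsoid):
        with pytest.raises(ValueError):
            antenna_frame(study_ellipsoid, 3.0, 0.0)


class TestSurfaceParameterization:
    def test_round_trip_identity(self, study_ellipsoid):
        rng = np.random.default_rng(3)
        th = rng.uniform(0.1, study_ellipsoid.theta_max, 50)
        ph = rng.uniform(0.0, 2 * np.pi, 50)
        pts = study_ellipsoid.surface_point(th, ph)
        th2, ph2 = study_ellipsoid.surface_coords(pts)
        assert np.allclose(th, th2, atol=1e-10)
        assert np.allclose(np.mod(ph, 2 * np.pi), np.mod(ph2, 2 * np.pi),
                           atol=1e-10)

    def test_trimmed_extent_matches_radius_plus_offset(self, study_ellipsoid):
        assert study_ellipsoid.trimmed_extent_z == pytest.approx(221.0)


class TestGridSpreading:
    def test_two_points_on_sphere_antipodal(self):
        e = hp.Ellipsoid(radii=(50.0, 50.0, 50.0))
        g = hp.spread_surface_grid(e, 2, seed=0, n_starts=4)
        d = np.linalg.norm(g.points[0] - g.points[1])
        assert d == pytest.approx(100.0, rel=1e-3)

    def test_four_points_on_unit_sphere_tetrahedron(self):
        e = hp.Ellipsoid(radii=(1.0, 1.0, 1.0))
        g = hp.spread_surface_grid(e, 4, seed=0, n_starts=8)
        X = g.points
        dists = [np.linalg.norm(X[i] - X[j])
                 for i in range(4) for j in range(i + 1, 4)]
        # regular tetrahedron: all pairwise distances sqrt(8/3)
        assert np.allclose(dists, np.sqrt(8.0 / 3.0), rtol=1e-3)

    def test_deterministic_under_seed(self, sphere_bolus):
        a = hp.spread_surface_grid(sphere_bolus, 10, seed=5, n_starts=2)
        b = hp.spread_surface_grid(sphere_bolus, 10, seed=5, n_starts=2)
        assert np.array_equal(a.thetas, b.thetas)
        assert np.array_equal(a.phis, b.phis)

    def test_respects_theta_max(self, study_ellipsoid):
        g = hp.spread_surface_grid(study_ellipsoid, 30, seed=0, n_starts=2)
        assert np.all(g.thetas <= study_ellipsoid.theta_max + 1e-9)

    def test_spacing_shrinks_with_density(self, study_ellipsoid):
        # average over two seeds; nearest-neighbor spacing must shrink as
        # the grid becomes denser
        sizes = (20, 40, 80)
        means = []
        for n in sizes:
            vals = [hp.spread_surface_grid(study_ellipsoid, n, seed=s,
                                           n_starts=2).max_nn
                    for s in (0, 1)]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_size_search_reaches_target(self):
        e = hp.Ellipsoid(radii=(60.0, 60.0, 60.0))
        n = hp.size_search(e, target_distance_mm=45.0, n_start=8, seed=0)
        g = hp.spread_surface_grid(e, n, seed=0, n_starts=2)
        assert g.max_nn < 45.0

    def test_uniform_sampling_respects_bounds(self, study_ellipsoid):
        rng = np.random.default_rng(0)
        th, ph = uniform_surface_sample(study_ellipsoid, 200, rng)
        assert np.all(th <= study_ellipsoid.theta_max)


class TestPatchLookup:
    def test_node_query_returns_node(self, small_grid):
        for i in (0, 5, 11):
            nodes, w, clamped = locate_patch(small_grid, small_grid.thetas[i],
                                             small_grid.phis[i])
            assert not clamped
            k = np.argmax(w)
            assert nodes[k] == i
            assert w[k] == pytest.approx(1.0, abs=1e-9)

    def test_centroid_query_near_equal_weights(self, small_grid):
        tri = small_grid.triangles[0]
        st_ = np.sin(small_grid.thetas[tri])
        U = np.stack([st_ * np.cos(small_grid.phis[tri]),
                      st_ * np.sin(small_grid.phis[tri]),
                      np.cos(small_grid.thetas[tri])], axis=-1)
        q = U.mean(axis=0)
        q /= np.linalg.norm(q)
        nodes, w, _ = locate_patch(small_grid, np.arccos(q[2]),
                                   np.arctan2(q[1], q[0]))
        assert set(nodes.tolist()) == set(tri.tolist())
        assert np.allclose(w, 1.0 / 3.0, atol=0.02)

    def test_weights_match_cross_product_area_oracle(self, small_grid):
        rng = np.random.default_rng(8)
        for _ in range(10):
            tri = small_grid.triangles[rng.integers(small_grid.n_patches)]
            lam = rng.dirichlet(np.ones(3) * 3.0)
            while lam.min() < 0.15:  # keep the query strictly interior
                lam = rng.dirichlet(np.ones(3) * 3.0)
            st_ = np.sin(small_grid.thetas[tri])
            U = np.stack([st_ * np.cos(small_grid.phis[tri]),
                          st_ * np.sin(small_grid.phis[tri]),
                          np.cos(small_grid.thetas[tri])], axis=-1)
            q = lam @ U
            q /= np.linalg.norm(q)
            nodes, w, _ = locate_patch(small_grid, np.arccos(q[2]),
                                       np.arctan2(q[1], q[0]))
            # independent area computation with raw cross products
            P = small_grid.points[nodes]
            e = small_grid.ellipsoid
            Q = e.surface_point(np.arccos(q[2]), np.arctan2(q[1], q[0]))
            n_hat = np.cross(P[1] - P[0], P[2] - P[0])
            n_hat /= np.linalg.norm(n_hat)
            Qp = Q - np.dot(Q - P[0], n_hat) * n_hat
            areas = np.array([
                np.linalg.norm(np.cross(P[1] - Qp, P[2] - Qp)),
                np.linalg.norm(np.cross(P[2] - Qp, P[0] - Qp)),
                np.linalg.norm(np.cross(P[0] - Qp, P[1] - Qp))]) / 2.0
            assert np.allclose(w, areas / areas.sum(), atol=1e-6)
            assert w.sum() == pytest.approx(1.0)
            assert np.all(w >= 0)

    def test_out_of_coverage_clamped_and_flagged(self, study_ellipsoid):
        g = hp.spread_surface_grid(study_ellipsoid, 25, seed=0, n_starts=2)
        _, _, clamped = locate_patch(g, study_ellipsoid.theta_max + 0.3, 1.0)
        assert clamped


class TestClearanceConstraints:
    def test_coincident_poses_infeasible(self, study_ellipsoid):
        p = antenna_frame(study_ellipsoid, 1.0, 0.5)
        pair, _ = clearance_constraints([p, p])
        assert pair[0, 1] < 0

    def test_antipodal_poses_feasible(self, sphere_bolus):
        a = antenna_frame(sphere_bolus, np.pi / 2, 0.0)
        b = antenna_frame(sphere_bolus, np.pi / 2, np.pi)
        pair, _ = clearance_constraints([a, b])
        assert pair[0, 1] > 0

    def test_symmetry_under_index_swap(self, study_ellipsoid):
        rng = np.random.default_rng(4)
        for _ in range(5):
            th = rng.uniform(0.2, study_ellipsoid.theta_max, 2)
            ph = rng.uniform(0, 2 * np.pi, 2)
            poses = [antenna_frame(study_ellipsoid, t, p)
                     for t, p in zip(th, ph)]
            pair, _ = clearance_constraints(poses)
            assert pair[0, 1] == pytest.approx(pair[1, 0])

    def test_eye_exclusion_blocks_nearby_pose(self, study_ellipsoid):
        eye = (np.array([30.0, 85.0, -20.0]), 12.0)
        proj, _ = study_ellipsoid.radial_projection(eye[0])
        th, ph = study_ellipsoid.surface_coords(proj)
        near = antenna_frame(study_ellipsoid, float(th), float(ph))
        far = antenna_frame(study_ellipsoid, 0.3, np.pi)
        _, vals = clearance_constraints([near, far], eye_exclusions=[eye],
                                        ellipsoid=study_ellipsoid)
        assert vals[0, 0] < 0 < vals[1, 0]
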