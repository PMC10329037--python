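"""Generators and oracles: cap geometry, membrane theory, grids, cells."""

import numpy as np
import pytest

from cmsm import (FootprintSpec, ShapeSpec, axisymmetric_oracle,
                  fit_spherical_cap, make_cap_mesh, make_cells,
                  make_point_cloud, make_traction_grid, measure_pressure,
                  spheroid_meridian, tube_oracle)
from cmsm.inference import BoundaryTractionPrediction
from tests.conftest import DP


class TestCapMeshes:
    def test_sphere_cap_radius_identity(self, sphere_mesh):
        # diameter 100, inflation 0.5 -> h = 25, R = (25^2+50^2)/(2*25)
        fit = fit_spherical_cap(sphere_mesh, FootprintSpec.circle(50))
        assert fit.R == pytest.approx(62.5, rel=1e-3)
        assert fit.h == pytest.approx(25.0, rel=1e-3)

    def test_tube_central_cross_section_is_circular_arc(self, tube14_mesh):
        h = 0.9 * 25.0
        Rc = (h * h + 625.0) / (2 * h)
        v = tube14_mesh.vertices
        central = np.abs(v[:, 0]) < 50.0
        y, z = v[central, 1], v[central, 2]
        r = np.hypot(y, z + (Rc - h))
        assert np.allclose(r, Rc, rtol=1e-6)

    def test_refinement_quadruples_vertices_and_reduces_error(self):
        counts, errs = [], []
        for edge in (5.0, 2.5):
            spec = ShapeSpec.spherical(100, 0.5, edge_length=edge)
            mesh = make_cap_mesh(spec)
            counts.append(mesh.n_vertices)
            c = np.array([0.0, 0.0, 25.0 - 62.5])
            # vertices are exact; the geometric error is the chordal sag
            # of the flat faces, measured at face centroids
            cents = mesh.vertices[mesh.faces].mean(axis=1)
            errs.append(np.max(np.abs(
                np.linalg.norm(cents - c, axis=1) - 62.5)))
        assert counts[1] / counts[0] == pytest.approx(4.0, rel=0.25)
        assert errs[1] < 0.5 * errs[0]

    def test_infeasible_inflation_rejected(self):
        with pytest.raises(ValueError):
            ShapeSpec.spherical(100, 1.5)
        with pytest.raises(ValueError):
            ShapeSpec.rect_tube(50, 4.0, 1.1)

    def test_ellipsoid_cap_footprint_and_height(self, ellipse13_mesh):
        loop = ellipse13_mesh.vertices[ellipse13_mesh.boundary_loop]
        r = (loop[:, 0] / 90) ** 2 + (loop[:, 1] / 30) ** 2
        assert np.allclose(r, 1.0, atol=0.02)
        assert ellipse13_mesh.height == pytest.approx(0.8 * 30.0, rel=1e-3)

    def test_meshes_are_deterministic(self):
        spec = ShapeSpec.spherical(50, 0.6)
        m1, m2 = make_cap_mesh(spec), make_cap_mesh(spec)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.faces, m2.faces)


class TestAxisymmetricOracle:
    def test_sphere_limit_is_young_laplace(self):
        spec = ShapeSpec.spherical(100, 0.5)
        z, r = spheroid_meridian(spec)
        oc = axisymmetric_oracle(z, r, DP)
        assert np.allclose(oc.N_phi, DP * 62.5 / 2, rtol=1e-3)
        assert np.allclose(oc.N_theta, DP * 62.5 / 2, rtol=2e-3)

    def test_cylinder_closed_form(self):
        # constant-radius profile: hoop dP*r, meridional dP*r/2
        z = np.linspace(0, 100, 200)
        r = np.full_like(z, 25.0)
        oc = axisymmetric_oracle(z, r, DP)
        assert np.allclose(oc.N_phi, DP * 25.0 / 2, rtol=1e-6)
        assert np.allclose(oc.N_theta, DP * 25.0, rtol=1e-3)

    def test_prolate_spheroid_self_check(self):
        spec = ShapeSpec.spheroid(60, 1.5, 0.9, edge_length=5.0)
        z, r = spheroid_meridian(spec, n=600)
        oc = axisymmetric_oracle(z, r, DP)
        assert np.max(oc.balance_residual()) < 1e-8

    def test_non_monotone_profile_rejected(self):
        z = np.array([0, 1, 1, 2, 3, 4, 5, 6.0])
        r = np.array([5, 5, 5, 5, 5, 5, 5, 5.0])
        with pytest.raises(ValueError, match="monotone"):
            axisymmetric_oracle(z, r, DP)

    def test_tube_oracle_half_cylinder_limit(self):
        hoop, ax = tube_oracle(50.0, 1.0, DP)
        assert hoop == pytest.approx(DP * 25.0)
        assert ax == pytest.approx(DP * 25.0 / 2)
        # lower inflation: axial/hoop below 1/2
        hoop2, ax2 = tube_oracle(50.0, 0.5, DP)
        assert ax2 / hoop2 < 0.5


def flat_ring_prediction(footprint, sigma_rz, l_T, n=512):
    pts2 = footprint.boundary_points(n)
    pts = np.c_[pts2, np.zeros(n)]
    s = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts2, axis=0), axis=1))])
    return BoundaryTractionPrediction(
        arc_length=s, points=pts, sigma_rz=np.full(n, sigma_rz), l_T=l_T,
        tension_vectors=np.c_[np.zeros((n, 2)), -np.full(n, sigma_rz)])


class TestTractionGridGenerator:
    def test_noiseless_round_trip_recovers_pressure(self):
        fp = FootprintSpec.circle(50)
        bp = flat_ring_prediction(fp, 1570.0, 15.7)
        grid = make_traction_grid(fp, DP, bp, 15.7, spacing=2.0, noise_sd=0.0)
        assert measure_pressure(grid).dP == pytest.approx(DP)

    def test_net_vertical_force_balances_for_rectangles(self):
        # downward dP * A vs upward ring sigma_rz/l_T over the band:
        # with sigma_rz = dP*A/P (P = perimeter) the construction balances
        fp = FootprintSpec.rectangle(200, 50)
        srz = DP * fp.area / 500.0
        bp = flat_ring_prediction(fp, srz, 15.7)
        grid = make_traction_grid(fp, DP, bp, 15.7, spacing=1.5, noise_sd=0.0)
        assert abs(grid.net_vertical_force()) < 0.05 * DP * fp.area

    def test_seeded_noise_is_reproducible(self):
        fp = FootprintSpec.circle(30)
        bp = flat_ring_prediction(fp, 1000.0, 15.7)
        g1 = make_traction_grid(fp, DP, bp, 15.7, noise_sd=5.0, seed=9)
        g2 = make_traction_grid(fp, DP, bp, 15.7, noise_sd=5.0, seed=9)
        assert np.array_equal(g1.Tz, g2.Tz)

    def test_polar_anisotropy_follows_boundary_tension(self, ellipse13_result,
                                                       ellipse13_spec):
        bp = ellipse13_result.predict_boundary_traction(15.7)
        grid = make_traction_grid(ellipse13_spec.footprint, DP, bp, 15.7,
                                  spacing=2.0, noise_sd=0.0)
        from cmsm import extract_polar_tractions
        prof = extract_polar_tractions(grid, 15.7, n_bins=9)
        # flat sides of the ellipse (beta -> 90) carry higher T_z
        assert prof.values[-1] > 2.0 * prof.values[0]


class TestMakeCells:
    def test_single_cell_valid(self, sphere_mesh):
        cells = make_cells(sphere_mesh, 1, seed=0)
        assert len(cells) == 1
        assert len(cells[0].outline) >= 5

    def test_deterministic_under_seed(self, sphere_mesh):
        c1 = make_cells(sphere_mesh, 20, kappa=3.0, seed=5)
        c2 = make_cells(sphere_mesh, 20, kappa=3.0, seed=5)
        assert all(np.array_equal(a.outline, b.outline)
                   for a, b in zip(c1, c2))

    def test_centroids_on_surface(self, sphere_mesh):
        cells = make_cells(sphere_mesh, 50, seed=1)
        c = np.array([cell.centroid for cell in cells])
        R, zc = 62.5, 25.0 - 62.5
        d = np.abs(np.linalg.norm(c - [0, 0, zc], axis=1) - R)
        assert np.max(d) < 0.2  # flat-facet sag only

    def test_strong_bias_aligns_cells(self, ellipse13_mesh, ellipse13_result):
        from cmsm import cell_stress_angle, fit_cell_ellipse
        cells = make_cells(ellipse13_mesh, 120, kappa=50.0,
                           direction_field=ellipse13_result.stress.dir_I,
                           seed=2)
        angles = []
        for cell in cells:
            try:
                e = fit_cell_ellipse(cell, ellipse13_mesh)
            except ValueError:
                continue
            a = cell_stress_angle(e, ellipse13_result.stress)
            if not np.isnan(a):
                angles.append(a)
        assert np.median(angles) < 10.0


class TestMakePointCloud:
    def test_zero_jitter_points_on_surface(self, sphere_mesh):
        pts = make_point_cloud(sphere_mesh, 7.5, jitter_sd=0.0, seed=0)
        R, zc = 62.5, 25.0 - 62.5
        d = np.abs(np.linalg.norm(pts - [0, 0, zc], axis=1) - R)
        assert np.max(d) < 0.05  # chordal sag of the flat facets

    def test_count_scales_with_slice_density(self, sphere_mesh):
        pts = make_point_cloud(sphere_mesh, 7.5, point_spacing=5.0, seed=0)
        assert 100 <= len(pts) <= 2000

    def test_bit_identical_under_fixed_seed(self, sphere_mesh):
        p1 = make_point_cloud(sphere_mesh, 7.5, jitter_sd=0.5, seed=3)
        p2 = make_point_cloud(sphere_mesh, 7.5, jitter_sd=0.5, seed=3)
        assert np.array_equal(p1, p2)
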