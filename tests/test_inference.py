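"""The cMSM solver: Laplace limit, decomposition, regularization, boundary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmsm import (CurvedMonolayerStress, PressureInput, RegularizationConfig,
                  ShapeSpec, StressField, calibrate_l_T, laplace_tension,
                  make_cap_mesh, predict_boundary_traction, principal_stress)
from cmsm.inference import IllPosedError
from tests.conftest import DP


class TestLaplaceTension:
    @pytest.mark.parametrize("dP,R,expected", [
        (200.0, 50.0, 5.0),
        (100.0, 100.0, 5.0),
        (0.0, 50.0, 0.0),
    ])
    def test_closed_form(self, dP, R, expected):
        assert laplace_tension(dP, R) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            laplace_tension(-1.0, 50.0)
        with pytest.raises(ValueError):
            laplace_tension(100.0, 0.0)


class TestPrincipalStress:
    def test_isotropic_tensor_degenerate_marked(self, sphere_mesh):
        comps = np.tile([5000.0, 0.0, 5000.0], (sphere_mesh.n_vertices, 1))
        f = StressField(sphere_mesh, comps)
        assert np.allclose(f.sigma_I, 5.0)
        assert np.allclose(f.sigma_II, 5.0)
        assert np.all(f.isotropic_mask)

    def test_diagonal_tensor(self, sphere_mesh):
        comps = np.tile([3000.0, 0.0, 1000.0], (sphere_mesh.n_vertices, 1))
        f = StressField(sphere_mesh, comps)
        sI, sII, (dI, dII) = principal_stress(f)
        t1, t2 = sphere_mesh.tangent_frames
        assert np.allclose(sI, 3.0) and np.allclose(sII, 1.0)
        assert np.allclose(np.abs(np.einsum("ij,ij->i", dI, t1)), 1.0)
        assert np.allclose(np.abs(np.einsum("ij,ij->i", dII, t2)), 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_recomposition_identity(self, sphere_mesh, seed):
        rng = np.random.default_rng(seed)
        comps = rng.normal(0, 3000, (sphere_mesh.n_vertices, 3))
        f = StressField(sphere_mesh, comps)
        sI, sII, (dI, dII) = principal_stress(f)
        assert np.all(sI >= sII)
        # recompose sigma = sum_i sigma_i d_i (x) d_i in the vertex frame
        t1, t2 = sphere_mesh.tangent_frames
        a1 = np.einsum("ij,ij->i", dI, t1)
        a2 = np.einsum("ij,ij->i", dI, t2)
        b1 = np.einsum("ij,ij->i", dII, t1)
        b2 = np.einsum("ij,ij->i", dII, t2)
        s11 = 1000 * (sI * a1 * a1 + sII * b1 * b1)
        s12 = 1000 * (sI * a1 * a2 + sII * b1 * b2)
        s22 = 1000 * (sI * a2 * a2 + sII * b2 * b2)
        rec = np.c_[s11, s12, s22]
        assert np.allclose(rec, comps, rtol=1e-10, atol=1e-6)


class TestInference:
    def test_sphere_matches_young_laplace(self, sphere_result):
        R = (25.0 ** 2 + 50.0 ** 2) / 50.0
        expected = laplace_tension(DP, R)
        mask = sphere_result.interior_mask()
        sI = sphere_result.stress.sigma_I[mask]
        sII = sphere_result.stress.sigma_II[mask]
        assert np.allclose(sI, expected, rtol=0.02)
        assert np.allclose(sII, expected, rtol=0.02)

    def test_zero_pressure_gives_zero_stress(self, sphere_mesh):
        res = CurvedMonolayerStress(sphere_mesh, 0.0).fit(lam=1e-3)
        assert np.allclose(res.stress.components, 0.0, atol=1e-9)

    def test_linearity_in_pressure(self, sphere_mesh):
        r1 = CurvedMonolayerStress(sphere_mesh, DP).fit(lam=1e-2)
        r2 = CurvedMonolayerStress(sphere_mesh, 2 * DP).fit(lam=1e-2)
        assert np.allclose(r2.stress.components, 2 * r1.stress.components,
                           rtol=1e-10, atol=1e-8)

    def test_near_flat_surface_rejected(self):
        spec = ShapeSpec.spherical(100.0, 0.002)  # k ~ 4e-5 1/um
        mesh = make_cap_mesh(spec)
        with pytest.raises(IllPosedError):
            CurvedMonolayerStress(mesh, DP).fit(lam=1e-3)

    def test_unit_pressure_mode_flagged(self, sphere_mesh):
        model = CurvedMonolayerStress(sphere_mesh, None)
        assert model.pressure.provenance == "assumed-unit"
        assert model.pressure.dP == 1.0
        with pytest.raises(ValueError):
            PressureInput.measured(-5.0)

    def test_summary_reports_fit(self, sphere_result):
        text = sphere_result.summary()
        assert "penalty weight" in text
        assert "sigma_I" in text


class TestRegularizationSelection:
    def test_clean_sphere_insensitive_over_two_decades(self, sphere_mesh):
        meds = []
        for lam in (1e-2, 1e-1, 1.0):
            res = CurvedMonolayerStress(sphere_mesh, DP).fit(lam=lam)
            meds.append(np.median(res.stress.mean_tension))
        assert (max(meds) - min(meds)) / min(meds) < 0.02

    def test_single_candidate_returned_fixed(self, sphere_mesh):
        res = CurvedMonolayerStress(sphere_mesh, DP).fit(
            lam="balance", candidates=[1e-2])
        assert res.regularization.method == "fixed"
        assert res.regularization.chosen == pytest.approx(1e-2)

    def test_jittered_mesh_prefers_positive_penalty(self, sphere_mesh):
        rng = np.random.default_rng(11)
        verts = sphere_mesh.vertices.copy()
        interior = ~sphere_mesh.is_boundary_vertex
        verts[interior] += rng.normal(0, 0.25, (interior.sum(), 3))
        from cmsm import SurfaceMesh
        noisy = SurfaceMesh.from_vertices_faces(verts, sphere_mesh.faces)
        model = CurvedMonolayerStress(noisy, DP)
        res = model.fit()
        cands = res.regularization.candidates
        assert res.regularization.chosen > cands[0]
        R = (25.0 ** 2 + 50.0 ** 2) / 50.0
        expected = laplace_tension(DP, R)
        res_min = model.fit(lam=float(cands[0]))
        mask = res.interior_mask()
        err_sel = np.median(np.abs(res.stress.sigma_I[mask] - expected))
        err_min = np.median(np.abs(res_min.stress.sigma_I[mask] - expected))
        assert err_sel < err_min

    def test_sweep_records_curve(self, sphere_result):
        reg = sphere_result.regularization
        assert reg.chosen in reg.candidates
        assert len(reg.residual_norms) == len(reg.candidates)
        assert np.all(reg.scores > 0)

    def test_invalid_candidates_rejected(self):
        with pytest.raises(ValueError):
            RegularizationConfig.sweep([0.0, 1.0])


class TestBoundaryTraction:
    def test_division_by_band_width(self, sphere_mesh):
        # constructed tension of 1570 Pa*um over l_T = 15.7 um -> 100 Pa
        comps = np.tile([5000.0, 0.0, 5000.0], (sphere_mesh.n_vertices, 1))
        f = StressField(sphere_mesh, comps)
        bp = predict_boundary_traction(f, sphere_mesh, l_T=15.7)
        assert np.allclose(bp.T_z * 15.7, bp.sigma_rz)

    def test_nonpositive_band_width_rejected(self, sphere_result):
        with pytest.raises(ValueError):
            sphere_result.predict_boundary_traction(l_T=0.0)

    def test_sphere_contact_angle_tension(self, sphere_result):
        # sigma_rz = sigma * sin(contact angle) for a spherical cap
        R = (25.0 ** 2 + 50.0 ** 2) / 50.0
        sin_phi = 50.0 / R
        expected = DP * R / 2 * sin_phi
        bp = sphere_result.predict_boundary_traction()
        assert np.median(bp.sigma_rz) == pytest.approx(expected, rel=0.03)

    def test_vertical_balance_sphere(self, sphere_result):
        A = np.pi * 50.0 ** 2
        assert sphere_result.contact_line_force() == pytest.approx(
            DP * A, rel=0.03)


class TestCalibrateLT:
    def test_median_ratio(self):
        assert calibrate_l_T([1570.0], [100.0]) == pytest.approx(15.7)

    def test_single_pair_is_the_ratio(self):
        assert calibrate_l_T(1200.0, 100.0) == pytest.approx(12.0)

    def test_zero_traction_rejected(self):
        with pytest.raises(ValueError):
            calibrate_l_T([1570.0], [0.0])
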