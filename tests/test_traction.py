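"""Traction-grid observables: pressure, side and polar profiles, binning."""

import numpy as np
import pytest

from cmsm import (FootprintSpec, TractionGrid, bin_stress_strain, cell_density,
                  extract_polar_tractions, extract_side_tractions,
                  measure_pressure)


def uniform_grid(footprint, value, spacing=2.0, pad=40.0, noise=0.0, seed=0):
    """Grid with T_z = value inside the footprint, zero outside."""
    import shapely
    poly = footprint.polygon()
    minx, miny, maxx, maxy = poly.bounds
    x = np.arange(minx - pad, maxx + pad, spacing)
    y = np.arange(miny - pad, maxy + pad, spacing)
    X, Y = np.meshgrid(x, y, indexing="ij")
    inside = shapely.contains(poly, shapely.points(np.c_[X.ravel(), Y.ravel()]))
    Tz = np.where(inside.reshape(X.shape), value, 0.0)
    if noise:
        Tz = Tz + np.random.default_rng(seed).normal(0, noise, Tz.shape)
    zero = np.zeros_like(Tz)
    return TractionGrid(x=x, y=y, Tx=zero, Ty=zero.copy(), Tz=Tz,
                        footprint=footprint)


class TestMeasurePressure:
    def test_uniform_field(self):
        grid = uniform_grid(FootprintSpec.circle(50), -100.0)
        est = measure_pressure(grid)
        assert est.dP == pytest.approx(100.0)
        assert est.warning is None

    def test_noisy_field_within_sampling_error(self):
        grid = uniform_grid(FootprintSpec.circle(50), -150.0, noise=10.0, seed=1)
        est = measure_pressure(grid)
        assert est.dP == pytest.approx(150.0, abs=3.0)

    def test_all_zero_grid_warns_deflated(self):
        grid = uniform_grid(FootprintSpec.circle(50), 0.0)
        est = measure_pressure(grid)
        assert est.dP == pytest.approx(0.0)
        assert "deflated" in est.warning

    def test_too_few_points_rejected(self):
        grid = uniform_grid(FootprintSpec.circle(10), -100.0, spacing=4.0)
        with pytest.raises(ValueError, match="central region"):
            measure_pressure(grid)


class TestSideTractions:
    def paint_band(self, footprint, side_values, band=15.7, spacing=1.5):
        """Zero inside, per-side constant T_z on the outer band."""
        w = footprint.parameters["width"]
        h = footprint.parameters["height"]
        grid = uniform_grid(footprint, 0.0, spacing=spacing)
        X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
        for key, val in side_values.items():
            if key == "x-":
                m = (X < -w / 2) & (X >= -w / 2 - band) & (np.abs(Y) <= h / 2)
            elif key == "x+":
                m = (X > w / 2) & (X <= w / 2 + band) & (np.abs(Y) <= h / 2)
            elif key == "y-":
                m = (Y < -h / 2) & (Y >= -h / 2 - band) & (np.abs(X) <= w / 2)
            else:
                m = (Y > h / 2) & (Y <= h / 2 + band) & (np.abs(X) <= w / 2)
            grid.Tz[m] = val
        return grid

    def test_constructed_long_short_ratio(self):
        fp = FootprintSpec.rectangle(200, 50)
        grid = self.paint_band(fp, {"x-": 50, "x+": 50, "y-": 100, "y+": 100})
        prof = extract_side_tractions(grid, band_width=15.7)
        vals = dict(zip(prof.labels, prof.values))
        long_vals = [v for k, v in vals.items() if "long" in k]
        short_vals = [v for k, v in vals.items() if "short" in k]
        assert np.allclose(long_vals, 100.0)
        assert np.allclose(short_vals, 50.0)
        assert np.mean(long_vals) / np.mean(short_vals) == pytest.approx(2.0)

    def test_square_four_fold_symmetry(self):
        fp = FootprintSpec.rectangle(50, 50)
        grid = self.paint_band(fp, {"x-": 80, "x+": 80, "y-": 80, "y+": 80})
        prof = extract_side_tractions(grid, band_width=15.7)
        assert np.max(prof.values) / np.min(prof.values) < 1.01

    def test_band_outside_grid_rejected(self):
        fp = FootprintSpec.rectangle(50, 50)
        grid = uniform_grid(fp, -100.0, pad=5.0)
        with pytest.raises(ValueError, match="outside"):
            extract_side_tractions(grid, band_width=30.0)

    def test_non_rectangular_footprint_rejected(self):
        grid = uniform_grid(FootprintSpec.circle(50), -100.0)
        with pytest.raises(ValueError, match="rectangular"):
            extract_side_tractions(grid, band_width=10.0)


class TestPolarTractions:
    def paint_polar(self, a, b, fun, band=15.7, spacing=1.5):
        fp = FootprintSpec.ellipse(a, b)
        grid = uniform_grid(fp, 0.0, spacing=spacing)
        import shapely
        import shapely.geometry as sgeom
        X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
        pts = shapely.points(np.c_[X.ravel(), Y.ravel()])
        poly = fp.polygon()
        inside = shapely.contains(poly, pts).reshape(X.shape)
        dist = shapely.distance(
            sgeom.LineString(poly.exterior.coords), pts).reshape(X.shape)
        bandm = (~inside) & (dist <= band)
        t_ref = np.linspace(0, np.pi / 2, 512)
        from scipy.spatial import cKDTree
        tree = cKDTree(np.c_[a * np.cos(t_ref), b * np.sin(t_ref)])
        _, idx = tree.query(np.c_[np.abs(X[bandm]), np.abs(Y[bandm])])
        grid.Tz[bandm] = fun(np.degrees(t_ref[idx]))
        return grid

    def test_painted_sin_squared_profile_recovered(self):
        fun = lambda beta: 50 + 50 * np.sin(np.radians(beta)) ** 2
        grid = self.paint_polar(90, 60, fun)
        prof = extract_polar_tractions(grid, band_width=15.7, n_bins=9)
        expected = fun(np.array(prof.labels))
        assert np.allclose(prof.values, expected, rtol=0.06)

    def test_circle_as_ellipse_is_flat(self):
        grid = self.paint_polar(60, 60 - 1e-9, lambda beta: 80.0 + 0 * beta)
        prof = extract_polar_tractions(grid, band_width=15.7, n_bins=9)
        assert np.nanmax(prof.values) / np.nanmin(prof.values) < 1.02

    def test_single_bin_is_global_median(self):
        grid = self.paint_polar(90, 60, lambda beta: beta + 10.0)
        prof = extract_polar_tractions(grid, band_width=15.7, n_bins=1)
        assert len(prof.values) == 1
        assert prof.values[0] > 0

    def test_quadrant_folding_idempotent_on_symmetric_fields(self):
        fun = lambda beta: 30 + beta
        grid = self.paint_polar(90, 60, fun)
        p9 = extract_polar_tractions(grid, band_width=15.7, n_bins=9)
        # folding already-symmetric data changes nothing bin-wise
        grid.Tz = np.abs(grid.Tz)  # symmetric by construction
        p9b = extract_polar_tractions(grid, band_width=15.7, n_bins=9)
        assert np.allclose(p9.values, p9b.values, equal_nan=True)


class TestCellDensity:
    @pytest.mark.parametrize("cin,cbound,A,expected", [
        (10, 4, 1000.0, 0.012),
        (0, 0, 1000.0, 0.0),
        (20, 6, np.pi * 50 ** 2, 23 / (np.pi * 2500)),
    ])
    def test_formula(self, cin, cbound, A, expected):
        assert cell_density(cin, cbound, A) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cell_density(10, 4, 0.0)
        with pytest.raises(ValueError):
            cell_density(-1, 0, 100.0)


class TestBinStressStrain:
    def test_three_identical_pairs_one_bin(self):
        df = bin_stress_strain([0.5, 0.5, 0.5], [5.0, 5.0, 5.0], 0.1)
        assert len(df) == 1
        assert df["sigma_mean"].iloc[0] == pytest.approx(5.0)
        assert df["sigma_sd"].iloc[0] == pytest.approx(0.0)

    def test_sparse_bins_dropped(self):
        df = bin_stress_strain([0.1, 0.12, 0.5, 0.52], [1, 2, 3, 4], 0.1)
        assert len(df) == 0

    def test_linear_relation_recovered(self):
        rng = np.random.default_rng(21)
        eps = rng.uniform(0, 1, 200)
        sig = 4 + 2 * eps + rng.normal(0, 0.3, 200)
        df = bin_stress_strain(eps, sig, 0.1)
        slope = np.polyfit(df["eps_a"], df["sigma_mean"], 1)[0]
        assert slope == pytest.approx(2.0, abs=0.3)
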