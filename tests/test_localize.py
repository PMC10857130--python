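"""Gaussian plume fitting, peak seeding, size estimation and calibration."""

import numpy as np
import pytest

from sersmap.localize import (
    PlumeFit,
    calibrate_size,
    find_peaks,
    fit_gaussians,
    fitted_diameter,
    smooth_map,
)
from sersmap.scan import ConcentrationMap, GridGeometry
from sersmap.simulate import SourceSpec, plume_field


def plume_map(geometry, centers, sigmas, strengths=None):
    strengths = strengths or [1.0] * len(centers)
    field = sum(
        plume_field(SourceSpec("BZD", c, s, a), geometry)
        for c, s, a in zip(centers, sigmas, strengths)
    )
    return ConcentrationMap(geometry, field / field.max())


class TestSmoothMap:
    def test_zero_sigma_is_identity(self, geometry):
        cmap = plume_map(geometry, [(7.5, 7.5)], [(2.0, 2.0)])
        out = smooth_map(cmap, 0.0)
        np.testing.assert_array_equal(out.values, cmap.values)

    def test_reflective_blur_conserves_total(self, geometry):
        from scipy import ndimage

        cmap = plume_map(geometry, [(7.5, 7.5)], [(2.0, 2.0)])
        blurred = ndimage.gaussian_filter(cmap.values, 1.5, mode="reflect")
        assert blurred.sum() == pytest.approx(cmap.values.sum(), rel=1e-6)

    def test_spike_spreads_to_neighbors(self, small_geometry):
        v = np.zeros((6, 6))
        v[3, 3] = 1.0
        out = smooth_map(ConcentrationMap(small_geometry, v), 1.0)
        # normalization puts the (reduced) center back at 1; neighbors rise
        assert out.values[3, 3] == 1.0
        assert (out.values[2:5, 2:5] > 0).all()

    def test_negative_sigma_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            smooth_map(ConcentrationMap(small_geometry, np.zeros((6, 6))), -1.0)


class TestFindPeaks:
    def test_single_gaussian_single_seed(self, geometry):
        cmap = plume_map(geometry, [(5.2, 9.8)], [(1.5, 1.5)])
        seeds = find_peaks(cmap, 3)
        assert len(seeds) == 1
        r, c = seeds[0]
        assert abs((c + 0.5) * geometry.pitch - 5.2) < geometry.pitch
        assert abs((r + 0.5) * geometry.pitch - 9.8) < geometry.pitch

    def test_two_separated_gaussians_two_seeds(self, geometry):
        cmap = plume_map(
            geometry, [(3.5, 3.5), (11.5, 11.5)], [(1.5, 1.5), (1.5, 1.5)]
        )
        seeds = find_peaks(cmap, 2)
        assert len(seeds) == 2
        rows = sorted(s[0] for s in seeds)
        assert abs(rows[0] - 8) <= 1 and abs(rows[1] - 27) <= 1

    def test_flank_wiggle_rejected_by_prominence(self, geometry):
        """A small bump riding on a plume flank is tall in absolute height but
        has almost no prominence, so it must not seed a second source."""
        field = plume_field(SourceSpec("BZD", (7.5, 7.5), (2.0, 2.0), 1.0), geometry)
        bump = plume_field(SourceSpec("BZD", (7.5, 4.3), (0.5, 0.5), 0.03), geometry)
        v = field + bump
        cmap = ConcentrationMap(geometry, v / v.max())
        seeds = find_peaks(cmap, 3)
        assert len(seeds) == 1

    def test_constant_map_warns_and_returns_none(self, small_geometry):
        cmap = ConcentrationMap(small_geometry, np.zeros((6, 6)))
        with pytest.warns(UserWarning):
            assert find_peaks(cmap, 1) == []


class TestFitGaussians:
    def test_noiseless_recovery_within_one_percent(self, geometry):
        cmap = plume_map(geometry, [(7.5, 7.5)], [(2.0, 2.0)])
        fit = fit_gaussians(cmap, 1)[0]
        assert fit.sigma_x == pytest.approx(2.0, rel=0.01)
        assert fit.sigma_y == pytest.approx(2.0, rel=0.01)
        half_pixel = geometry.pitch / 2
        assert abs(fit.x0 - 7.5) < half_pixel
        assert abs(fit.y0 - 7.5) < half_pixel
        assert fit.offset == pytest.approx(0.0, abs=1e-3)

    def test_noisy_recovery_within_a_pixel(self, geometry):
        rng = np.random.default_rng(42)
        field = plume_field(SourceSpec("BZD", (7.5, 7.5), (2.0, 2.0), 1.0), geometry)
        noisy = np.clip(field + rng.normal(0, 0.05, field.shape), 0, None)
        cmap = ConcentrationMap(geometry, noisy / noisy.max())
        fit = fit_gaussians(cmap, 1)[0]
        assert abs(fit.x0 - 7.5) < geometry.pitch
        assert abs(fit.y0 - 7.5) < geometry.pitch
        assert fit.sigma_x == pytest.approx(2.0, rel=0.10)
        assert fit.sigma_y == pytest.approx(2.0, rel=0.10)

    def test_two_corner_sources_both_recovered(self, geometry):
        # left-bottom and right-up, > 9 mm apart
        cmap = plume_map(
            geometry, [(3.5, 11.5), (11.5, 3.5)], [(1.5, 1.5), (1.5, 1.5)]
        )
        fits = fit_gaussians(cmap, 2)
        centers = sorted((f.x0, f.y0) for f in fits)
        assert abs(centers[0][0] - 3.5) < geometry.pitch
        assert abs(centers[0][1] - 11.5) < geometry.pitch
        assert abs(centers[1][0] - 11.5) < geometry.pitch
        assert abs(centers[1][1] - 3.5) < geometry.pitch

    def test_constant_map_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            fit_gaussians(ConcentrationMap(small_geometry, np.zeros((6, 6))), 1)

    def test_k_out_of_range_rejected(self, geometry):
        cmap = plume_map(geometry, [(7.5, 7.5)], [(2.0, 2.0)])
        with pytest.raises(ValueError):
            fit_gaussians(cmap, 4)


class TestFittedDiameter:
    @pytest.mark.parametrize("sx,sy,expected", [(2.0, 2.0, 2.0), (1.0, 3.0, 2.0)])
    def test_formula_and_symmetry(self, sx, sy, expected):
        fit = PlumeFit(1.0, 7.5, 7.5, sx, sy, 0.0, 0.0)
        assert fitted_diameter(fit) == expected
        swapped = PlumeFit(1.0, 7.5, 7.5, sy, sx, 0.0, 0.0)
        assert fitted_diameter(swapped) == fitted_diameter(fit)

    def test_recovered_from_noiseless_plume(self, geometry):
        cmap = plume_map(geometry, [(7.5, 7.5)], [(1.5, 1.5)])
        fit = fit_gaussians(cmap, 1)[0]
        assert fitted_diameter(fit) == pytest.approx(1.5, abs=0.015)


class TestCalibrateSize:
    def test_perfect_line(self):
        pairs = [(d, 0.5 * d) for d in (1.0, 2.0, 3.0, 4.0)]
        cal = calibrate_size(pairs)
        assert cal.slope == pytest.approx(0.5)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0)

    def test_hand_computed_r_squared(self):
        cal = calibrate_size([(1, 1), (2, 3), (3, 2)])
        assert cal.r_squared == pytest.approx(0.25)
        assert cal.slope == pytest.approx(0.5)
        assert cal.intercept == pytest.approx(1.0)

    def test_r_squared_invariant_under_affine_actual_axis(self):
        rng = np.random.default_rng(3)
        actual = np.linspace(2, 5, 6)
        fitted = 0.4 * actual + rng.normal(0, 0.05, 6)
        base = calibrate_size(list(zip(actual, fitted)))
        shifted = calibrate_size(list(zip(3.0 * actual - 1.0, fitted)))
        assert shifted.r_squared == pytest.approx(base.r_squared)

    def test_degenerate_actuals_rejected(self):
        with pytest.raises(ValueError):
            calibrate_size([(2.0, 1.0), (2.0, 1.5)])
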