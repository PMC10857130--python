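"""Synthetic-scan and dataset generator: lineshapes, plumes, gaps, noise."""

import numpy as np
import pytest

from sersmap.scan import GridGeometry
from sersmap.simulate import (
    BASELINE,
    BZD,
    EBZD,
    GasSignature,
    NoiseModel,
    SourceSpec,
    default_axis,
    gap_mask,
    make_axis,
    plume_field,
    signature_spectrum,
    simulate_feature_dataset,
    simulate_scan,
)


class TestMakeAxis:
    def test_default_axis_span_and_members(self):
        axis = make_axis(602, 4, 308)
        assert len(axis) == 308
        assert axis.values[-1] == 1830
        for v in (1006, 1010, 1614):
            assert v in axis.values

    def test_anchored_at_1543_contains_high_wavenumber_triplet(self):
        axis = make_axis(1543, 4, 50)
        for v in (1603, 1607, 1611):
            assert v in axis.values

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_axis(602, 0, 308)
        with pytest.raises(ValueError):
            make_axis(602, 4, 1)


class TestSignatureSpectrum:
    def test_lorentzian_peak_maximum_and_fwhm(self):
        axis = make_axis(980, 2, 40)  # contains 1000 and 1000±10
        sig = GasSignature("x", ((1000.0, 20.0, 1.0),))
        s = signature_spectrum(sig, axis)
        assert s[axis.index_of(1000)] == pytest.approx(1.0)
        assert s[axis.index_of(990)] == pytest.approx(0.5)
        assert s[axis.index_of(1010)] == pytest.approx(0.5)

    def test_resolution_limited_merged_peak_at_1607(self):
        """Two peaks 11 cm^-1 apart merge into one apparent peak at 1607 on a
        4 cm^-1 grid anchored at 1603."""
        axis = make_axis(1543, 4, 50)
        sig = GasSignature(
            "pair", ((1603.0, 20.0, 1.0), (1614.0, 20.0, 1.0))
        )
        s = signature_spectrum(sig, axis)
        window = (axis.values >= 1595) & (axis.values <= 1620)
        argmax = axis.values[window][np.argmax(s[window])]
        assert argmax == 1607

    def test_gaussian_lineshape_fwhm(self):
        axis = make_axis(980, 2, 40)
        sig = GasSignature("x", ((1000.0, 20.0, 2.0),))
        s = signature_spectrum(sig, axis, lineshape="gaussian")
        assert s[axis.index_of(1000)] == pytest.approx(2.0)
        assert s[axis.index_of(990)] == pytest.approx(1.0)

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            GasSignature("empty", ())


class TestPlumeField:
    def test_maximum_at_source_pixel_center(self, geometry):
        # source exactly at the center of pixel (17, 17)
        from sersmap.scan import pixel_center_mm

        cx, cy = pixel_center_mm(17, 17, geometry)
        field = plume_field(SourceSpec("BZD", (cx, cy), (2.0, 2.0), 0.8), geometry)
        assert field[17, 17] == pytest.approx(0.8)
        assert field.max() == pytest.approx(0.8)

    def test_mirror_symmetry_about_source_column(self, geometry):
        from sersmap.scan import pixel_center_mm

        cx, cy = pixel_center_mm(17, 17, geometry)
        field = plume_field(SourceSpec("BZD", (cx, cy), (2.0, 2.0), 1.0), geometry)
        for d in (1, 3, 7):
            np.testing.assert_allclose(field[17, 17 - d], field[17, 17 + d])

    def test_grid_sum_matches_gaussian_integral(self, geometry):
        field = plume_field(SourceSpec("BZD", (7.5, 7.5), (2.0, 2.0), 1.0), geometry)
        expected = 2 * np.pi * 2.0 * 2.0 / geometry.pitch**2
        assert field.sum() == pytest.approx(expected, rel=0.01)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            SourceSpec("BZD", (7.5, 7.5), (0.0, 2.0), 1.0)


class TestGapMask:
    def test_default_band_count_is_140(self, geometry):
        mask = gap_mask(geometry)
        assert mask.sum() == 140  # 2·36 + 2·36 − 4 overlaps
        assert mask[12].all() and mask[24].all()
        assert mask[:, 12].all() and mask[:, 24].all()

    def test_zero_width_mask_empty(self, geometry):
        assert gap_mask(geometry, band_width=0).sum() == 0

    def test_transpose_invariance(self, geometry):
        mask = gap_mask(geometry)
        np.testing.assert_array_equal(mask, mask.T)

    def test_indivisible_layout_rejected(self):
        with pytest.raises(ValueError):
            gap_mask(GridGeometry(35, 35), sensors_per_side=3)


class TestSimulateScan:
    def test_default_scan_has_1296_spectra_of_308_channels(self, center_bzd_scan):
        assert center_bzd_scan.V.shape == (1296, 308)

    def test_zero_sources_zero_noise_gives_pure_baseline(self, geometry, axis):
        scan = simulate_scan(
            [], noise=NoiseModel(additive_sd=0, multiplicative_sd=0, seed=0),
            baseline_strength=0.3, background=0.0,
        )
        expected = 0.3 * signature_spectrum(BASELINE, axis)
        gaps = gap_mask(geometry).ravel()
        np.testing.assert_allclose(
            scan.V[~gaps], np.broadcast_to(expected, scan.V[~gaps].shape),
            atol=1e-12,
        )
        np.testing.assert_allclose(scan.V[gaps], 0.0)

    def test_center_source_peaks_at_center_pixels(self, clean_center_scan):
        axis = clean_center_scan.axis
        ch = axis.index_of(1006)
        k = int(np.argmax(clean_center_scan.V[:, ch]))
        row, col = divmod(k, 36)
        assert row in (17, 18) and col in (17, 18)

    def test_unknown_gas_rejected(self):
        with pytest.raises(KeyError):
            simulate_scan([SourceSpec("XYZ", (7.5, 7.5), (2.0, 2.0))])

    def test_seed_determinism(self):
        a = simulate_scan([SourceSpec("BZD", (7.5, 7.5), (2.0, 2.0))],
                          noise=NoiseModel(seed=3))
        b = simulate_scan([SourceSpec("BZD", (7.5, 7.5), (2.0, 2.0))],
                          noise=NoiseModel(seed=3))
        np.testing.assert_array_equal(a.V, b.V)

    def test_nonnegative_and_clip_audit(self, center_bzd_scan):
        assert center_bzd_scan.V.min() >= 0
        assert center_bzd_scan.metadata["clipped_fraction_signal_pixels"] < 0.01


class TestFeatureDataset:
    def test_reference_train_composition(self):
        ds = simulate_feature_dataset((68, 21, 13), seed=1)
        assert len(ds) == 102
        assert ds.class_counts() == {0: 68, 1: 21, 2: 13}

    def test_reference_test_composition(self):
        ds = simulate_feature_dataset((28, 14, 14), seed=2)
        assert len(ds) == 56
        assert ds.class_counts() == {0: 28, 1: 14, 2: 14}

    def test_seed_determinism(self):
        a = simulate_feature_dataset((10, 5, 5), seed=9)
        b = simulate_feature_dataset((10, 5, 5), seed=9)
        np.testing.assert_array_equal(a.spectra, b.spectra)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_feature_dataset((0, 0, 0))

    def test_gas_classes_peak_near_their_signatures(self):
        ds = simulate_feature_dataset((0, 5, 5), noise_sd=0.0, seed=4)
        axis = default_axis()
        for x, y in zip(ds.spectra, ds.labels):
            peak = axis.values[int(np.argmax(x))]
            target = 1006 if y == 1 else 1614
            assert abs(peak - target) <= 6  # ≤ 2 cm^-1 jitter + grid snap
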