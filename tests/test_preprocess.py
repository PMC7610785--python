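import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ramanev.preprocess import (
    PreprocessConfig,
    auc_normalize,
    crop,
    crop_cube,
    preprocess_cube,
    shape_baseline,
    shape_baseline_cube,
    subtract_system_background,
)
from ramanev.spectral import HyperCube, Spectrum, make_axis
from ramanev.synth import gaussian_peak


@pytest.fixture()
def flat_spectrum(full_axis):
    return Spectrum(full_axis, np.ones(full_axis.n_bins))


class TestCrop:
    def test_crop_keeps_requested_window(self, flat_spectrum):
        out = crop(flat_spectrum, 400.0, 3600.0)
        assert out.axis.values[0] >= 400.0 and out.axis.values[-1] <= 3600.0
        assert out.intensities.size == out.axis.n_bins

    def test_crop_is_idempotent(self, flat_spectrum):
        once = crop(flat_spectrum, 400.0, 3600.0)
        twice = crop(once, 400.0, 3600.0)
        assert np.array_equal(once.intensities, twice.intensities)
        assert once.axis == twice.axis

    def test_silent_region_crop(self, flat_spectrum):
        out = crop(flat_spectrum, 1800.0, 2800.0)
        assert out.axis.values.min() >= 1800.0
        assert out.axis.values.max() <= 2800.0

    def test_empty_overlap_rejected(self, flat_spectrum):
        with pytest.raises(ValueError):
            crop(flat_spectrum, 4000.0, 4100.0)


class TestShapeBaseline:
    def test_constant_spectrum_fully_assigned_to_baseline(self, full_axis):
        spectrum = Spectrum(full_axis, np.full(full_axis.n_bins, 3.7))
        corrected, baseline = shape_baseline(spectrum, 500.0)
        assert np.allclose(baseline.intensities, 3.7)
        assert np.allclose(corrected.intensities, 0.0)

    def test_exact_reconstruction(self, cropped_axis, rng):
        y = rng.normal(1.0, 0.3, cropped_axis.n_bins).cumsum() * 0.01 + 2.0
        spectrum = Spectrum(cropped_axis, y)
        corrected, baseline = shape_baseline(spectrum, 500.0)
        assert np.array_equal(corrected.intensities + baseline.intensities, y)

    def test_narrow_peak_on_ramp_keeps_its_area(self, cropped_axis):
        x = cropped_axis.values
        ramp = 1.0 + (x - x[0]) / (x[-1] - x[0]) * 2.0
        peak = gaussian_peak(cropped_axis, 1450.0, 25.0, 1.0)
        corrected, _ = shape_baseline(Spectrum(cropped_axis, ramp + peak), 500.0)
        window = (x >= 1450 - 100) & (x <= 1450 + 100)
        area = np.trapezoid(corrected.intensities[window], x[window])
        planted = 1.0 * 25.0 * np.sqrt(2 * np.pi)
        assert area == pytest.approx(planted, rel=0.05)

    def test_baseline_is_a_lower_envelope(self, cropped_axis):
        x = cropped_axis.values
        y = 2.0 + gaussian_peak(cropped_axis, 1000.0, 20.0, 1.5)
        _, baseline = shape_baseline(Spectrum(cropped_axis, y), 500.0)
        assert baseline.intensities.max() <= y.max() + 1e-12
        # corrected stays above the smoothing-induced tolerance
        corrected = y - baseline.intensities
        assert corrected.min() > -0.05 * y.max()

    def test_window_wider_than_spectrum_rejected(self):
        axis = make_axis(0.0, 110.0, 11.0)
        with pytest.raises(ValueError, match="exceeds"):
            shape_baseline(Spectrum(axis, np.ones(axis.n_bins)), 500.0)
        with pytest.raises(ValueError, match="fewer than 3"):
            shape_baseline(Spectrum(axis, np.ones(axis.n_bins)), 11.0)


class TestAucNormalize:
    def test_unit_area_after_normalization(self, cropped_axis):
        y = gaussian_peak(cropped_axis, 1450.0, 30.0, 5.0) + 0.2
        out = auc_normalize(Spectrum(cropped_axis, y))
        assert np.trapezoid(out.intensities, cropped_axis.values) == pytest.approx(1.0, abs=1e-9)
        assert not out.empty

    @given(scale=st.floats(min_value=1e-3, max_value=1e4))
    def test_scale_invariance(self, scale):
        axis = make_axis(400.0, 3600.0, 11.0)
        y = gaussian_peak(axis, 1450.0, 30.0, 2.0) + 0.1
        a = auc_normalize(Spectrum(axis, y))
        b = auc_normalize(Spectrum(axis, scale * y))
        assert np.allclose(a.intensities, b.intensities, rtol=1e-9, atol=1e-12)

    def test_all_zero_pixel_flagged_and_unchanged(self, cropped_axis):
        zero = Spectrum(cropped_axis, np.zeros(cropped_axis.n_bins))
        out = auc_normalize(zero)
        assert out.empty
        assert np.array_equal(out.intensities, zero.intensities)


class TestSystemBackground:
    def test_uniform_cube_subtracts_to_zero(self, cropped_axis):
        data = np.tile(np.linspace(1, 2, cropped_axis.n_bins), (6, 6, 1))
        cube = HyperCube(cropped_axis, data)
        exterior = np.zeros((6, 6), dtype=bool)
        exterior[:2] = True
        out = subtract_system_background(cube, exterior)
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_pairwise_differences_preserved_exactly(self, cropped_axis, rng):
        data = rng.normal(size=(5, 4, cropped_axis.n_bins))
        cube = HyperCube(cropped_axis, data)
        exterior = np.zeros((5, 4), dtype=bool)
        exterior[0] = True
        out = subtract_system_background(cube, exterior)
        assert np.allclose(
            out.data[1, 1] - out.data[3, 2], data[1, 1] - data[3, 2], atol=1e-12
        )

    def test_known_offset_recovered(self, cropped_axis, rng):
        offset = gaussian_peak(cropped_axis, 1050.0, 30.0, 2.0) + 0.5
        signal = np.zeros((6, 6, cropped_axis.n_bins))
        signal[2:4, 2:4] = gaussian_peak(cropped_axis, 2900.0, 40.0, 3.0)
        cube = HyperCube(cropped_axis, signal + offset)
        exterior = np.ones((6, 6), dtype=bool)
        exterior[2:4, 2:4] = False
        out = subtract_system_background(cube, exterior)
        assert np.allclose(out.data, signal, atol=1e-10)

    def test_empty_exterior_rejected(self, cropped_axis):
        cube = HyperCube(cropped_axis, np.zeros((4, 4, cropped_axis.n_bins)))
        with pytest.raises(ValueError, match="empty"):
            subtract_system_background(cube, np.zeros((4, 4), dtype=bool))


class TestFullChain:
    def test_pipeline_is_pure(self, noisy_phantom):
        cube, truth = noisy_phantom
        exterior = ~truth.cell_mask
        exterior[1:-1, 1:-1] &= ~truth.cell_mask[1:-1, 1:-1]
        config = PreprocessConfig()
        a = preprocess_cube(cube, config, exterior_mask=~truth.cell_mask)
        b = preprocess_cube(cube, config, exterior_mask=~truth.cell_mask)
        assert np.array_equal(a.data, b.data)

    def test_corrected_cube_matches_planted_mixture(self, clean_phantom):
        """After baseline removal and exterior subtraction the noise-free cube
        equals the planted peak mixture to within a few percent (L2)."""
        from ramanev.uptake import estimate_exterior_mask

        cube, truth = clean_phantom
        base = crop_cube(cube, 400.0, 3600.0)
        corrected, _ = shape_baseline_cube(base, 500.0)
        exterior = estimate_exterior_mask(corrected)
        out = subtract_system_background(corrected, exterior)
        sl = cube.axis.window_slice(400.0, 3600.0)
        planted = truth.clean_signal[..., sl]
        rel = np.linalg.norm(out.data - planted) / np.linalg.norm(planted)
        assert rel < 0.05

    def test_normalize_requires_positive_area_and_flags_empty(self, cropped_axis):
        data = np.zeros((4, 4, cropped_axis.n_bins))
        data[0, 0] = gaussian_peak(cropped_axis, 1450.0, 30.0, 1.0)
        cube = HyperCube(cropped_axis, data)
        config = PreprocessConfig(crop_range=(500.0, 3500.0), background_mode="none")
        out = preprocess_cube(cube, config)
        assert out.empty_mask is not None
        assert not out.empty_mask[0, 0]
        assert out.empty_mask[1, 1]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(crop_range=(3600.0, 400.0))
        with pytest.raises(ValueError):
            PreprocessConfig(shape_size=-1.0)
        with pytest.raises(ValueError):
            PreprocessConfig(background_mode="median")
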