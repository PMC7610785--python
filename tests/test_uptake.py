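from dataclasses import replace

import numpy as np
import pytest

from ramanev.bands import BandDefinition, band_auc, band_net_auc
from ramanev.config import PipelineConfig
from ramanev.pipeline import _preprocess_variants, process_cube
from ramanev.spectral import HyperCube
from ramanev.synth import (
    CellPhantomSpec,
    EvPixel,
    make_uptake_phantom_spec,
    simulate_cell_cube,
)
from ramanev.uptake import (
    CellMask,
    DEUTERIUM_BAND,
    detect_deuterium_pixels,
    extract_deuterium_spectra,
    membrane_distances,
    partition_signal,
    segment_cell,
    segment_cells,
)


from tests_support_brute import brute_force_signed_distances, random_connected_mask  # noqa: E402


class TestSegmentation:
    def test_phantom_cell_recovered_with_high_jaccard(self, clean_phantom, full_axis):
        cube, truth = clean_phantom
        clean = HyperCube(full_axis, truth.clean_signal)
        wc = band_auc(clean, BandDefinition("wc", 2800.0, 3000.0))
        cell = segment_cell(wc)
        inter = (cell.mask & truth.cell_mask).sum()
        union = (cell.mask | truth.cell_mask).sum()
        assert inter / union >= 0.95

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            segment_cell(np.ones((32, 32)))

    def test_largest_of_two_blobs_retained(self):
        img = np.zeros((40, 40))
        img[5:25, 5:25] = 1.0  # 400 px blob
        img[30:36, 30:36] = 1.0  # 36 px blob
        cell = segment_cell(img, closing_radius=0)
        assert cell.mask[10, 10] and not cell.mask[32, 32]

    def test_multi_cell_segmentation_labels_both(self):
        img = np.zeros((40, 40))
        img[5:20, 5:20] = 1.0
        img[25:38, 25:38] = 1.0
        cells = segment_cells(img, closing_radius=0, min_area=25)
        assert len(cells) == 2

    def test_membrane_is_eight_connected_boundary(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[3:9, 3:9] = True
        cell = CellMask(mask)
        assert cell.membrane.sum() == 20  # 6x6 square boundary
        assert not cell.membrane[5, 5]


class TestDetection:
    def test_noise_free_phantom_detects_exactly_planted_pixels(self, full_axis):
        planted = (EvPixel(20, 20, 1.0, "inside"), EvPixel(20, 21, 1.0, "inside"),
                   EvPixel(28, 24, 1.5, "inside"), EvPixel(10, 24, 0.8, "inside"),
                   EvPixel(24, 30, 2.0, "inside"))
        spec = CellPhantomSpec(ev_pixels=planted, noise_sd=0.0)
        cube, truth = simulate_cell_cube(spec, full_axis, seed=0)
        quant, _, exterior = _preprocess_variants(cube, PipelineConfig())
        dmap = band_net_auc(quant, DEUTERIUM_BAND)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            positive, info = detect_deuterium_pixels(dmap, exterior)
        assert {tuple(c) for c in np.argwhere(positive)} == {
            (p.row, p.col) for p in planted
        }

    def test_threshold_rule_recorded(self, noisy_phantom):
        cube, _ = noisy_phantom
        quant, _, exterior = _preprocess_variants(cube, PipelineConfig())
        dmap = band_net_auc(quant, DEUTERIUM_BAND)
        _, info = detect_deuterium_pixels(dmap, exterior, k=3.0)
        assert info["rule"] == "mean + 3.0*sd"
        assert info["threshold"] > info["exterior_mean"]

    def test_prune_removes_isolated_positives_only(self):
        values = np.zeros((10, 10))
        values[2, 2] = 5.0  # isolated
        values[6, 6] = 5.0
        values[6, 7] = 5.0  # pair
        from ramanev.uptake import ExteriorStats

        stats = ExteriorStats(mean=0.0, sd=0.5, n=50)
        positive, _ = detect_deuterium_pixels(values, stats, k=3.0, prune_isolated=True)
        assert not positive[2, 2]
        assert positive[6, 6] and positive[6, 7]


class TestMembraneDistances:
    def test_matches_brute_force_on_random_masks(self, rng):
        for size in (16, 33, 64):
            for _ in range(5):
                cell_mask = random_connected_mask(rng, size)
                cell = CellMask(cell_mask, pixel_size_um=0.5)
                positives = rng.random((size, size)) < 0.1
                got = membrane_distances(positives, cell)
                want = brute_force_signed_distances(positives, cell_mask, cell.membrane, 0.5)
                assert np.array_equal(got, want)

    def test_square_mask_centre_pixel(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:10, 0:10] = True
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = True
        cell = CellMask(mask, pixel_size_um=0.5)
        positives = np.zeros((10, 10), dtype=bool)
        positives[4, 4] = True
        want = brute_force_signed_distances(positives, mask, cell.membrane, 0.5)
        assert membrane_distances(positives, cell) == pytest.approx(want)

    def test_sign_convention(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[3:9, 3:9] = True
        cell = CellMask(mask, pixel_size_um=1.0)
        positives = np.zeros((12, 12), dtype=bool)
        positives[3, 3] = True  # on the membrane
        positives[5, 5] = True  # interior
        positives[0, 0] = True  # exterior, Chebyshev distance 3
        d = membrane_distances(positives, cell)  # row-major: (0,0), (3,3), (5,5)
        assert d[0] < 0
        assert d[1] == 0.0
        assert d[2] > 0

    def test_translation_invariance(self, rng):
        mask = random_connected_mask(rng, 24)
        positives = rng.random((24, 24)) < 0.15
        big = np.zeros((40, 40), dtype=bool)
        big_pos = np.zeros((40, 40), dtype=bool)
        big[7 : 7 + 24, 9 : 9 + 24] = mask
        big_pos[7 : 7 + 24, 9 : 9 + 24] = positives
        d0 = membrane_distances(positives, CellMask(mask))
        d1 = membrane_distances(big_pos, CellMask(big))
        assert np.allclose(np.sort(d0), np.sort(d1))

    def test_empty_membrane_rejected(self):
        with pytest.raises(ValueError):
            CellMask(np.zeros((5, 5), dtype=bool))


class TestPartition:
    def _square_cell(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:16, 4:16] = True
        return CellMask(mask, pixel_size_um=0.5)

    def test_all_interior_signal_is_100_inside(self):
        cell = self._square_cell()
        values = np.zeros((20, 20))
        positives = np.zeros((20, 20), dtype=bool)
        values[8, 8] = values[10, 10] = 3.0
        positives[8, 8] = positives[10, 10] = True
        assert partition_signal(values, positives, cell) == (100.0, 0.0)

    def test_equal_split_between_inside_and_outside(self):
        cell = self._square_cell()
        values = np.zeros((20, 20))
        positives = np.zeros((20, 20), dtype=bool)
        values[8, 8] = values[1, 1] = 2.0
        positives[8, 8] = positives[1, 1] = True
        pct_in, pct_out = partition_signal(values, positives, cell)
        assert pct_in == pytest.approx(50.0)
        assert pct_in + pct_out == pytest.approx(100.0, abs=1e-9)

    def test_membrane_signal_counts_as_associated(self):
        cell = self._square_cell()
        values = np.zeros((20, 20))
        positives = np.zeros((20, 20), dtype=bool)
        values[4, 8] = 1.0  # membrane pixel
        positives[4, 8] = True
        assert partition_signal(values, positives, cell)[0] == 100.0

    def test_no_positive_pixels_flagged_undefined(self):
        cell = self._square_cell()
        with pytest.warns(RuntimeWarning, match="undefined"):
            pct_in, pct_out = partition_signal(np.zeros((20, 20)), np.zeros((20, 20), bool), cell)
        assert np.isnan(pct_in) and np.isnan(pct_out)


class TestExtraction:
    def test_extracted_spectra_match_locations(self, clean_phantom, full_axis):
        cube, truth = clean_phantom
        positives = np.zeros(truth.cell_mask.shape, dtype=bool)
        for p in truth.ev_pixels[:5]:
            positives[p.row, p.col] = True
        cell = CellMask(truth.cell_mask)
        table, spectra = extract_deuterium_spectra(cube, positives, cell)
        assert len(table) == positives.sum()
        assert spectra.shape == (positives.sum(), full_axis.n_bins)
        first = table.iloc[0]
        assert np.array_equal(spectra[0], cube.data[int(first.row), int(first.col)])

    def test_interior_spectra_carry_cell_and_deuterium_signal(self, clean_phantom):
        """Interior deuterium pixels mix the EV tag with the surrounding cell
        (protein/lipid) signature."""
        cube, truth = clean_phantom
        inside = [p for p in truth.ev_pixels if p.placement == "inside"]
        positives = np.zeros(truth.cell_mask.shape, dtype=bool)
        for p in inside:
            positives[p.row, p.col] = True
        _, spectra = extract_deuterium_spectra(
            HyperCube(cube.axis, truth.clean_signal), positives
        )
        cd_bin = cube.axis.nearest_bin(2140.0)
        protein_bin = cube.axis.nearest_bin(1660.0)
        assert np.all(spectra[:, cd_bin] > 0)
        assert np.all(spectra[:, protein_bin] > 0)

    def test_surface_bound_spectra_are_deuterium_richer_than_interior(self, full_axis):
        """In a surface-binding phantom, membrane/exterior EV pixels show a
        higher deuterium-to-(protein+lipid) band ratio than interior ones."""
        spec = make_uptake_phantom_spec("surface_bound", seed=8, noise_sd=0.0)
        cube, truth = simulate_cell_cube(spec, full_axis, seed=8)
        clean = HyperCube(full_axis, truth.clean_signal)
        d = band_auc(clean, DEUTERIUM_BAND).values
        prot = band_auc(clean, BandDefinition("p", 1635.0, 1685.0)).values
        lip = band_auc(clean, BandDefinition("l", 1425.0, 1485.0)).values
        eps = 1e-9
        interior = [p for p in truth.ev_pixels if p.placement == "inside"]
        surface = [p for p in truth.ev_pixels if p.placement != "inside"]
        ratio = lambda p: d[p.row, p.col] / (prot[p.row, p.col] + lip[p.row, p.col] + eps)
        assert min(ratio(p) for p in surface) > max(ratio(p) for p in interior)

    def test_empty_mask_warns_and_returns_nothing(self, clean_phantom):
        cube, truth = clean_phantom
        with pytest.warns(RuntimeWarning, match="empty"):
            table, spectra = extract_deuterium_spectra(cube, np.zeros(truth.cell_mask.shape, bool))
        assert len(table) == 0 and spectra.shape[0] == 0


class TestEndToEndPhantom:
    def test_translated_phantom_keeps_distances_and_percentages(self, full_axis):
        spec = make_uptake_phantom_spec("internalised", seed=6, noise_sd=0.0)
        cube, _ = simulate_cell_cube(spec, full_axis, seed=6)
        res0 = process_cube(cube, PipelineConfig())

        shifted = replace(
            spec,
            shape=(56, 56),
            cell_center=(27.5, 29.5),  # default centre (23.5, 23.5) + (4, 6)
            cell_radii=(0.38 * 48, 0.40 * 48),
            ev_pixels=tuple(
                EvPixel(p.row + 4, p.col + 6, p.amplitude, p.placement) for p in spec.ev_pixels
            ),
        )
        cube1, _ = simulate_cell_cube(shifted, full_axis, seed=6)
        res1 = process_cube(cube1, PipelineConfig())
        assert np.allclose(
            np.sort(res0.report.distances_um), np.sort(res1.report.distances_um)
        )
        assert res0.report.pct_inside == pytest.approx(res1.report.pct_inside, abs=1e-9)
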