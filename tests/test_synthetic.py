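"""Generator correctness: peak shapes, mixture structure, scene layouts,
low-rank guarantees, and seeded determinism."""

import numpy as np
import pytest

from ramancs.io import WavenumberAxis
from ramancs.synthetic import (CYTOPLASM, DRUG, DRUG_PEAK_CM1, Endmember,
                               SceneSpec, add_spikes, default_axis,
                               make_cell_scene, make_endmember_spectrum,
                               make_mixture_series, make_tissue_scene,
                               tissue_test_spec)


class TestEndmemberSpectrum:
    def test_zero_peaks_rejected(self):
        with pytest.raises(ValueError, match="at least one peak"):
            Endmember("empty", peaks=())

    @pytest.mark.parametrize("profile", ["gaussian", "lorentzian"])
    def test_single_peak_apex_equals_amplitude(self, profile):
        axis = WavenumberAxis(np.linspace(600, 1800, 241))  # 1200 on the grid
        em = Endmember("one", peaks=((1200.0, 30.0, 2.5),), profile=profile)
        spectrum = make_endmember_spectrum(em, axis)
        apex = axis.nearest_index(1200.0)
        assert spectrum[apex] == pytest.approx(2.5)
        assert np.all(spectrum >= 0)

    def test_center_outside_axis_rejected(self, axis):
        em = Endmember("out", peaks=((5000.0, 30.0, 1.0),))
        with pytest.raises(ValueError, match="outside axis"):
            make_endmember_spectrum(em, axis)

    def test_two_nonoverlapping_peaks_integral_additivity(self):
        # quadrature oracle: integral of the sum equals the sum of the
        # single-peak integrals
        axis = WavenumberAxis(np.linspace(600, 1800, 2401))
        a = Endmember("a", peaks=((800.0, 20.0, 1.0),), profile="gaussian")
        b = Endmember("b", peaks=((1600.0, 25.0, 0.5),), profile="gaussian")
        both = Endmember("ab", peaks=a.peaks + b.peaks, profile="gaussian")
        x = axis.values
        total = np.trapezoid(make_endmember_spectrum(both, axis), x)
        parts = np.trapezoid(make_endmember_spectrum(a, axis), x) + np.trapezoid(
            make_endmember_spectrum(b, axis), x
        )
        assert total == pytest.approx(parts, rel=1e-10)


class TestMixtureSeries:
    def test_default_sweep_covers_60_to_80_in_2_percent_steps(self, noisy_mixture):
        assert np.array_equal(noisy_mixture.concentrations, np.arange(60.0, 81, 2))
        assert noisy_mixture.spectra.shape == (11 * 10, 300)

    def test_noiseless_spectrum_is_exact_mixture(self, noiseless_mixture):
        ds = noiseless_mixture
        w = make_endmember_spectrum(ds.truth_endmembers[0], ds.axis)
        s = make_endmember_spectrum(ds.truth_endmembers[1], ds.axis)
        f = ds.y[0] / 100.0
        np.testing.assert_allclose(ds.spectra[0], f * w + (1 - f) * s, rtol=1e-12)

    def test_noiseless_matrix_has_rank_two(self, noiseless_mixture):
        # singular-value oracle: two distinct fractions of two endmembers
        sv = np.linalg.svd(noiseless_mixture.spectra, compute_uv=False)
        assert sv[1] / sv[0] > 1e-6
        assert sv[2] / sv[0] < 1e-12

    def test_baseline_adds_bounded_extra_rank(self):
        ds = make_mixture_series(noise_sd=0.0, baseline_amplitude=0.5, seed=0)
        sv = np.linalg.svd(ds.spectra, compute_uv=False)
        # cubic baseline spans <= 4 extra directions
        assert sv[6] / sv[0] < 1e-10

    def test_seeded_reproducibility(self):
        a = make_mixture_series(seed=42)
        b = make_mixture_series(seed=42)
        np.testing.assert_array_equal(a.spectra, b.spectra)

    def test_fraction_bounds_and_replicates_validated(self):
        with pytest.raises(ValueError, match="fractions"):
            make_mixture_series(fractions=[0.0, 50.0])
        with pytest.raises(ValueError, match="replicates"):
            make_mixture_series(n_replicates=1)


class TestCellScene:
    def test_default_grid_is_32_by_36(self, cell_scene):
        cube, truth = cell_scene
        assert cube.grid == (32, 36)
        assert truth.shape == (32, 36)

    def test_three_percent_of_1152_pixels_is_35_drug_pixels(self, cell_scene):
        _, truth = cell_scene
        assert abs(int((truth == 2).sum()) - round(0.03 * 32 * 36)) <= 1

    def test_labels_partition_all_pixels(self, cell_scene):
        _, truth = cell_scene
        assert set(np.unique(truth)) == {0, 1, 2}

    def test_drug_blobs_sit_inside_the_cell(self, cell_scene):
        from scipy.ndimage import binary_dilation

        _, truth = cell_scene
        near_drug = binary_dilation(truth == 2)
        assert not np.any(near_drug & (truth == 0))

    def test_rare_fraction_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_cell_scene(rare_fraction=0.0)
        with pytest.raises(ValueError):
            make_cell_scene(rare_fraction=25.0)

    def test_tiny_rare_fraction_still_places_one_pixel(self):
        _, truth = make_cell_scene(rare_fraction=0.01)
        assert (truth == 2).sum() == 1

    def test_drug_peak_visible_only_in_drug_pixels(self, clean_cell_scene):
        cube, truth = clean_cell_scene
        channel = cube.axis.nearest_index(DRUG_PEAK_CM1)
        values = cube.intensities[:, channel].reshape(cube.grid)
        assert values[truth == 2].min() > values[truth != 2].max()

    def test_shared_peak_in_other_class_rejected(self):
        bad_cyto = Endmember("cytoplasm", peaks=CYTOPLASM.peaks + ((1168.0, 16.0, 0.5),))
        with pytest.raises(ValueError, match="share the drug peak"):
            make_cell_scene(endmembers={
                "background": Endmember("background", peaks=((800.0, 400.0, 0.1),)),
                "cytoplasm": bad_cyto,
                "drug": DRUG,
            })

    def test_seeded_reproducibility(self):
        spec = SceneSpec(grid=(32, 36), noise_sd=0.02, baseline_amplitude=0.05, seed=9)
        a_cube, a_truth = make_cell_scene(spec)
        b_cube, b_truth = make_cell_scene(spec)
        np.testing.assert_array_equal(a_cube.intensities, b_cube.intensities)
        np.testing.assert_array_equal(a_truth, b_truth)


class TestTissueScene:
    def test_clean_scene_has_rank_three(self):
        spec = SceneSpec(grid=(16, 36), baseline_amplitude=0.0, noise_sd=0.0, seed=0)
        cube, truth = make_tissue_scene(spec)
        sv = np.linalg.svd(cube.intensities, compute_uv=False)
        assert sv[2] / sv[0] > 1e-6
        assert sv[3] / sv[0] < 1e-12
        assert set(np.unique(truth)) == {0, 1, 2}

    def test_large_baseline_dominates_every_spectrum(self):
        spec = SceneSpec(grid=(8, 9), baseline_amplitude=10.0, noise_sd=0.0, seed=0)
        cube, _ = make_tissue_scene(spec)
        clean = make_tissue_scene(
            SceneSpec(grid=(8, 9), baseline_amplitude=0.0, noise_sd=0.0, seed=0)
        )[0]
        # per-spectrum max is set by the baseline, not any Raman peak
        assert np.all(cube.intensities.max(axis=1) > 5 * clean.intensities.max())

    def test_full_size_default_matches_study_geometry(self):
        cube, truth = make_tissue_scene()
        assert cube.grid == (65, 145)
        assert truth.shape == (65, 145)

    def test_fewer_than_three_classes_rejected(self):
        with pytest.raises(ValueError, match="3 classes"):
            make_tissue_scene(endmembers={"background": TISSUE_BG_STANDIN,
                                          "gray": TISSUE_BG_STANDIN})

    def test_noiseless_signal_component_is_nonnegative(self):
        spec = tissue_test_spec(noise_sd=0.0, seed=2)
        cube, _ = make_tissue_scene(spec)
        assert cube.intensities.min() >= 0.0


TISSUE_BG_STANDIN = Endmember("background", peaks=((900.0, 500.0, 0.1),))


class TestSpikes:
    def _flat_cube(self, rows, cols, n_channels=16, seed=0):
        spec = SceneSpec(grid=(rows, cols), seed=seed, n_channels=n_channels)
        return make_tissue_scene(spec)[0]

    def test_zero_rate_leaves_cube_unchanged(self):
        cube = self._flat_cube(4, 4)
        spiked = add_spikes(cube, spike_rate=0.0, amplitude=5.0, seed=1)
        np.testing.assert_array_equal(spiked.intensities, cube.intensities)

    def test_rate_one_single_pixel_gets_exactly_one_spike(self):
        cube = self._flat_cube(1, 1)
        spiked = add_spikes(cube, spike_rate=1.0, amplitude=7.0, seed=1)
        delta = spiked.intensities - cube.intensities
        assert np.count_nonzero(delta) == 1
        assert delta.max() == pytest.approx(7.0)

    def test_spike_count_is_binomial(self):
        # 3-sigma binomial bound: 10000 pixels at rate 0.01 -> 100 +/- 30
        cube = self._flat_cube(100, 100)
        spiked = add_spikes(cube, spike_rate=0.01, amplitude=5.0, seed=3)
        count = spiked.meta["spikes"]
        sigma = np.sqrt(10000 * 0.01 * 0.99)
        assert abs(count - 100) <= 3 * sigma

    def test_nonpositive_amplitude_rejected(self):
        cube = self._flat_cube(2, 2)
        with pytest.raises(ValueError, match="amplitude"):
            add_spikes(cube, spike_rate=0.5, amplitude=0.0)


class TestSceneSpecConfig:
    def test_round_trips_through_flat_text(self):
        spec = SceneSpec(grid=(7, 9), baseline_amplitude=2.5, noise_sd=0.125,
                         shot_noise=True, spike_rate=0.01, seed=11, n_channels=64)
        assert SceneSpec.from_config(spec.to_config()) == spec
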