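"""Imaging endpoints: PCA against an eigendecomposition oracle, k-means
against exhaustive enumeration, drug detection, label alignment, and
accuracy metrics."""

import itertools

import numpy as np
import pytest

from ramancs.imaging import (ClusterMap, align_labels, compare_pc_loadings,
                             detect_drug_pixels, kmeans, pca_fit,
                             segmentation_accuracy)
from ramancs.synthetic import DRUG_PEAK_CM1


class TestPCA:
    def test_collinear_columns_explained_by_first_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=50)
        X = np.column_stack([t, 2 * t])
        result = pca_fit(X, n_components=2)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_tiny_case_matches_covariance_eigendecomposition(self):
        X = np.array([[1.0, 2.0], [3.0, 1.0], [2.0, 5.0]])
        result = pca_fit(X, n_components=2)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (X.shape[0] - 1))
        order = np.argsort(evals)[::-1]
        for i, j in enumerate(order):
            v = evecs[:, j]
            v = v * np.sign(v[np.argmax(np.abs(v))])
            np.testing.assert_allclose(result.components[i], v, atol=1e-10)

    def test_loadings_orthonormal_and_reconstruction_exact(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        result = pca_fit(X, n_components=6)
        np.testing.assert_allclose(result.components @ result.components.T,
                                   np.eye(6), atol=1e-8)
        reconstructed = result.scores @ result.components + result.mean
        np.testing.assert_allclose(reconstructed, X, atol=1e-8)

    def test_out_of_range_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            pca_fit(np.ones((5, 3)), n_components=4)


class TestKMeans:
    def test_separated_blobs_partitioned_exactly(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.1, size=(20, 2))
        b = rng.normal(10, 0.1, size=(20, 2))
        cm = kmeans(np.vstack([a, b]), 2, seed=0)
        assert len(set(cm.labels[:20])) == 1
        assert len(set(cm.labels[20:])) == 1
        assert cm.labels[0] != cm.labels[-1]

    def test_k_equals_n_points_gives_zero_inertia(self):
        points = np.arange(5.0)[:, None]
        cm = kmeans(points, 5, seed=0)
        assert cm.inertia == pytest.approx(0.0, abs=1e-12)

    def test_six_point_case_matches_exhaustive_enumeration(self):
        # brute-force oracle: globally optimal 2-partition by inertia
        points = np.array([0.0, 0.5, 1.0, 7.0, 7.5, 10.0])[:, None]

        def inertia(labels):
            total = 0.0
            for g in set(labels):
                grp = points[np.array(labels) == g]
                total += float(((grp - grp.mean(axis=0)) ** 2).sum())
            return total

        best = min(
            inertia(assign)
            for assign in itertools.product([0, 1], repeat=6)
            if len(set(assign)) == 2
        )
        cm = kmeans(points, 2, seed=0, n_init=10)
        assert cm.inertia == pytest.approx(best, rel=1e-10)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError, match="k"):
            kmeans(np.ones((4, 2)), 0)
        with pytest.raises(ValueError, match="distinct"):
            kmeans(np.ones((4, 2)), 2)


class TestDetectDrugPixels:
    def test_noiseless_scene_detected_exactly(self, clean_cell_scene):
        # mean + k*sd is the outlier-style rule suited to a rare class on
        # raw intensities (an Otsu 2-way split on this 3-population
        # histogram legitimately separates background from cell instead)
        cube, truth = clean_cell_scene
        detected = detect_drug_pixels(cube, DRUG_PEAK_CM1, rule="mean_plus_ksd")
        np.testing.assert_array_equal(detected, truth == 2)

    def test_uniform_scene_yields_empty_detection(self, small_axis):
        from ramancs.io import HyperspectralCube

        cube = HyperspectralCube(small_axis, (4, 4), np.ones((16, 64)))
        detected = detect_drug_pixels(cube, 1168.0, rule="mean_plus_ksd")
        assert not detected.any()

    def test_fixed_threshold_sweep_is_monotone_in_tpr(self, cell_scene):
        cube, truth = cell_scene
        drug = (truth == 2)
        tprs = []
        for t in np.linspace(2.0, 0.0, 15):
            detected = detect_drug_pixels(cube, DRUG_PEAK_CM1, rule="fixed",
                                          threshold=t)
            tprs.append((detected & drug).sum() / drug.sum())
        assert np.all(np.diff(tprs) >= 0)

    def test_wavenumber_outside_axis_rejected(self, cell_scene):
        cube, _ = cell_scene
        with pytest.raises(ValueError, match="outside axis"):
            detect_drug_pixels(cube, 3000.0)


class TestAlignLabels:
    def test_identical_maps_align_to_identity(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        aligned = align_labels(truth.copy(), truth)
        np.testing.assert_array_equal(aligned.labels, truth)
        assert segmentation_accuracy(aligned, truth) == 100.0

    def test_swapped_labels_fully_recovered(self):
        truth = np.array([0, 0, 1, 1, 1, 0])
        swapped = 1 - truth
        aligned = align_labels(swapped, truth)
        np.testing.assert_array_equal(aligned.labels, truth)

    def test_matches_exhaustive_permutation_search(self):
        rng = np.random.default_rng(3)
        truth = rng.integers(0, 3, size=16)
        pred = rng.integers(0, 3, size=16)
        best = max(
            np.sum(np.array([perm[p] for p in pred]) == truth)
            for perm in itertools.permutations(range(3))
        )
        aligned = align_labels(pred, truth)
        assert np.sum(aligned.labels == truth) == best

    def test_agreement_invariant_to_predicted_relabeling(self):
        rng = np.random.default_rng(4)
        truth = rng.integers(0, 3, size=30)
        pred = rng.integers(0, 3, size=30)
        base = np.sum(align_labels(pred, truth).labels == truth)
        for perm in itertools.permutations(range(3)):
            relabeled = np.array([perm[p] for p in pred])
            assert np.sum(align_labels(relabeled, truth).labels == truth) == base

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="size"):
            align_labels(np.zeros(4, dtype=int), np.zeros(5, dtype=int))


class TestSegmentationAccuracy:
    def test_perfect_prediction_scores_100_in_both_modes(self):
        truth = np.array([0, 1, 1, 2])
        assert segmentation_accuracy(truth, truth) == 100.0
        assert segmentation_accuracy(truth, truth, class_of_interest=2) == 100.0

    def test_present_class_never_predicted_scores_zero(self):
        truth = np.array([0, 0, 2, 2])
        pred = np.array([0, 0, 0, 0])
        assert segmentation_accuracy(pred, truth, class_of_interest=2) == 0.0

    def test_one_wrong_pixel_of_nine(self):
        truth = np.zeros(9, dtype=int)
        pred = truth.copy()
        pred[4] = 1
        assert segmentation_accuracy(pred, truth) == pytest.approx(800 / 9)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            segmentation_accuracy(np.zeros(4, dtype=int), np.zeros(4, dtype=int),
                                  class_of_interest=3)


class TestComparePCLoadings:
    def test_self_comparison_matches_everywhere(self):
        rng = np.random.default_rng(5)
        result = pca_fit(rng.normal(size=(30, 8)), n_components=4)
        prefix, sims, flags = compare_pc_loadings(result, result)
        assert prefix == 4
        assert flags.all()
        np.testing.assert_allclose(sims, 1.0, atol=1e-12)

    def test_corrupted_first_component_gives_zero_prefix(self):
        rng = np.random.default_rng(6)
        a = pca_fit(rng.normal(size=(30, 8)), n_components=3)
        b = pca_fit(rng.normal(size=(30, 8)), n_components=3)
        b.components[0] = rng.normal(size=8)
        prefix, _, _ = compare_pc_loadings(a, b)
        assert prefix == 0

    def test_axis_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        a = pca_fit(rng.normal(size=(20, 8)), n_components=2)
        b = pca_fit(rng.normal(size=(20, 6)), n_components=2)
        with pytest.raises(ValueError, match="axes"):
            compare_pc_loadings(a, b)
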