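"""Stepwise-LDA pixel classification, ROI extraction, acquisition merging."""

import numpy as np
import pytest

from nutspec import cube, segmentation, simulate


def _two_class_pixels(n_per=100, bands=51, informative=17, sep=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, bands))
    y = np.repeat([0, 1], n_per)
    X[:, informative] += sep * y
    return X, y


def _single_band_f(X, y):
    """Exhaustive per-band one-way F scan (enter-step oracle at p = 0)."""
    n = X.shape[0]
    out = []
    for j in range(X.shape[1]):
        a, b = X[y == 0, j], X[y == 1, j]
        within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        total = ((X[:, j] - X[:, j].mean()) ** 2).sum()
        out.append((n - 2) * (total / within - 1.0))
    return np.asarray(out)


class TestStepwiseLDA:
    @pytest.mark.parametrize("seed", range(5))
    def test_informative_band_enters_first(self, seed):
        """Oracle: the first entered band is the exhaustive-scan argmax,
        which is the planted informative band."""
        X, y = _two_class_pixels(seed=1000 + seed)
        model = segmentation.train_stepwise_lda(X, y)
        oracle = int(np.argmax(_single_band_f(X, y)))
        assert model.selected_band_indices[0] == oracle == 17
        # pure-noise bands can clear F-to-enter by chance (multiplicity over
        # 50 candidates), but the selection must stay far from exhaustive
        assert len(model.selected_band_indices) <= 10

    def test_shuffled_labels_rarely_select(self):
        """Permutation null on a single candidate band: partial F exceeds
        3.84 ~ F(1, n-2) upper 5 % point, so ~95 of 100 shuffles select
        nothing (bound set 3 binomial sd below the theoretical rate)."""
        none_selected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 1))
            labels = rng.permutation(np.repeat([0, 1], 60))
            try:
                segmentation.train_stepwise_lda(X, labels, max_vars=1)
            except ValueError:
                none_selected += 1
        assert none_selected >= 89

    def test_three_informative_bands_keep_selection_small(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 60))
        y = np.repeat([0, 1], 200)
        for j, s in [(10, 2.0), (30, 1.5), (50, 1.0)]:
            X[:, j] += s * y
        model = segmentation.train_stepwise_lda(X, y)
        assert len(model.selected_band_indices) <= 5
        assert 10 in model.selected_band_indices

    def test_separable_training_is_perfect(self):
        X, y = _two_class_pixels(sep=12.0, seed=2)
        model = segmentation.train_stepwise_lda(X, y)
        pred = (X[:, model.selected_band_indices] @ model.weights > model.intercept)
        assert (pred.astype(int) == y).all()

    def test_single_class_errors(self):
        X, _ = _two_class_pixels()
        with pytest.raises(ValueError, match="2 classes"):
            segmentation.train_stepwise_lda(X, np.zeros(X.shape[0]))

    def test_constant_bands_skipped(self):
        X, y = _two_class_pixels()
        X[:, 3] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            model = segmentation.train_stepwise_lda(X, y)
        assert 3 not in model.selected_band_indices


class TestClassification:
    def test_scene_pixel_accuracy(self, noisy_scene, trained_lda):
        absorb = cube.absorbance_from_raw(noisy_scene.b.raw, noisy_scene.b.frames)
        mask = segmentation.classify_pixels(trained_lda, absorb)
        truth = noisy_scene.b.truth.mask > 0
        assert (mask.astype(bool) == truth).mean() >= 0.99

    def test_all_background_scene_has_no_kernels(self, trained_lda):
        wl = simulate.default_band_grid()
        bg = simulate._background_absorbance(wl)
        data = np.broadcast_to(bg, (40, 50, wl.size)).copy()
        c = cube.HyperCube(data, wl, "absorbance")
        mask = segmentation.classify_pixels(trained_lda, c)
        assert mask.sum() == 0

    def test_band_mismatch_errors(self, trained_lda):
        c = cube.HyperCube(np.zeros((4, 4, 3)), [1.0, 2.0, 3.0], "absorbance")
        with pytest.raises(ValueError, match="band"):
            segmentation.classify_pixels(trained_lda, c)


class TestROIExtraction:
    def test_scene_yields_exactly_ten_rois(self, noisy_scene, trained_lda):
        absorb = cube.absorbance_from_raw(noisy_scene.a.raw, noisy_scene.a.frames)
        mask = segmentation.classify_pixels(trained_lda, absorb)
        rois = segmentation.extract_objects(mask)
        assert len(rois) == 10

    def test_diagonal_touch_is_two_objects(self):
        mask = np.zeros((12, 12), dtype=int)
        mask[2:5, 2:5] = 1
        mask[5:8, 5:8] = 1  # touches only at the (4,4)/(5,5) diagonal
        rois = segmentation.extract_objects(mask, min_area=4)
        assert len(rois) == 2

    def test_speckle_below_min_area_dropped(self):
        mask = np.zeros((30, 30), dtype=int)
        mask[5:15, 5:15] = 1           # 100 px kernel
        mask[25, 25] = 1               # lone speckle
        rois = segmentation.extract_objects(mask, min_area=50)
        assert len(rois) == 1 and rois[0].area == 100

    def test_ids_in_reading_order(self):
        mask = np.zeros((20, 20), dtype=int)
        mask[12:15, 1:4] = 1
        mask[1:4, 10:13] = 1
        rois = segmentation.extract_objects(mask, min_area=4)
        assert rois[0].centroid[0] < rois[1].centroid[0]
        assert [r.kernel_id for r in rois] == [1, 2]


class TestSpectraAndMerging:
    def test_uniform_roi_mean_is_the_pixel_spectrum(self):
        wl = np.array([1000.0, 1003.25])
        data = np.ones((5, 5, 2)) * np.array([0.3, 0.7])
        c = cube.HyperCube(data, wl, "absorbance")
        roi = segmentation.KernelROI(1, np.array([[0, 0], [1, 1], [2, 2]]), 3, (1.0, 1.0))
        np.testing.assert_allclose(segmentation.mean_spectrum(c, roi), [0.3, 0.7])

    def test_merge_identity_when_acquisitions_agree(self):
        spec = {1: np.array([1.0, 2.0]), 2: np.array([3.0, 4.0])}
        merged = segmentation.merge_acquisitions(spec, spec, {1: 1, 2: 2})
        np.testing.assert_allclose(merged[1], spec[1])

    def test_unpaired_kernel_errors(self):
        spec = {1: np.zeros(2), 2: np.zeros(2)}
        with pytest.raises(ValueError, match="unpaired"):
            segmentation.merge_acquisitions(spec, {1: np.zeros(2)}, {1: 1})

    def test_noise_off_merged_spectrum_equals_truth(self, silent_scene, trained_lda):
        """The merged per-kernel spectrum reproduces sum(c_k eps_k) exactly."""
        sigs = simulate.default_signatures()
        spectra = {}
        for tag, acq in (("a", silent_scene.a), ("b", silent_scene.b)):
            absorb = cube.absorbance_from_raw(acq.raw, acq.frames)
            mask = segmentation.classify_pixels(trained_lda, absorb)
            rois = segmentation.extract_objects(mask)
            to_truth = segmentation.match_rois_to_truth(rois, acq.truth.mask)
            spectra[tag] = {
                to_truth[r.kernel_id]: segmentation.mean_spectrum(absorb, r) for r in rois
            }
        merged = segmentation.merge_acquisitions(
            spectra["a"], spectra["b"], silent_scene.pairing
        )
        for kid, spec in merged.items():
            expected = silent_scene.a.truth.compositions[kid] @ sigs.matrix()
            assert np.abs(spec - expected).max() < 1e-8

    def test_rotation_pairing_matches_truth(self, noisy_scene, trained_lda):
        rois = {}
        for tag, acq in (("a", noisy_scene.a), ("b", noisy_scene.b)):
            absorb = cube.absorbance_from_raw(acq.raw, acq.frames)
            mask = segmentation.classify_pixels(trained_lda, absorb)
            rois[tag] = segmentation.extract_objects(mask)
        pairing = segmentation.pair_rois_by_rotation(
            rois["a"], rois["b"], noisy_scene.a.truth.mask.shape
        )
        truth_a = segmentation.match_rois_to_truth(rois["a"], noisy_scene.a.truth.mask)
        truth_b = segmentation.match_rois_to_truth(rois["b"], noisy_scene.b.truth.mask)
        for ka, kb in pairing.items():
            assert noisy_scene.pairing[truth_a[ka]] == truth_b[kb]
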