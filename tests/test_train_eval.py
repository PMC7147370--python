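"""Training loop, augmentation, metrics, and the signed-rank test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from stochact import (
    TrainConfig,
    accuracy,
    augment,
    augment_pair,
    pixel_f1,
    resize_for_model,
    resize_mask_back,
    tiny_cnn,
    tiny_segmenter,
    train,
    wilcoxon_signed_rank,
)
from stochact.train_eval import evaluation_report, kfold_indices, pairwise_wilcoxon


class TestAugment:
    def test_identity_when_rng_draws_identity(self, rng, monkeypatch):
        """With no flips and unit scales the image passes through unchanged."""
        import stochact.train_eval as te
        monkeypatch.setattr(te, "_augment_params", lambda shape, r: (False, False, 1.0, 1.0))
        img = rng.random((16, 16, 3))
        np.testing.assert_array_equal(te.augment(img, rng), img)

    def test_shape_preserved(self, rng):
        img = rng.random((21, 33, 3))
        for _ in range(10):
            assert augment(img, rng).shape == img.shape

    def test_deterministic_under_seed(self, rng):
        img = rng.random((16, 16, 3))
        a1 = augment(img, np.random.default_rng(5))
        a2 = augment(img, np.random.default_rng(5))
        np.testing.assert_array_equal(a1, a2)

    def test_empty_image_rejected(self, rng):
        with pytest.raises(ValueError):
            augment(np.empty((0, 0, 3)), rng)

    def test_mask_stays_aligned_with_image(self, rng):
        """Augmenting an (image, mask) pair keeps labels pixel-aligned.

        The image encodes its mask in the red channel, so after identical
        geometric transforms, thresholding the image must reproduce the mask.
        Flips must align exactly; rescales may differ on the object
        boundary only (bilinear image vs nearest-neighbor labels).
        """
        import stochact.train_eval as te
        mask = np.zeros((24, 24), dtype=int)
        mask[6:14, 8:20] = 1
        img = np.zeros((24, 24, 3))
        img[:, :, 0] = mask
        for flips in ((True, False), (True, True)):
            params = flips + (1.0, 1.0)
            ai = te._apply_augment(img, params, order=1)
            am = te._apply_augment(mask.astype(float), params, order=0)
            np.testing.assert_array_equal((ai[:, :, 0] > 0.5).astype(int),
                                          np.rint(am).astype(int))
        for seed in range(5):
            ai, am = augment_pair(img, mask, np.random.default_rng(seed))
            assert set(np.unique(am)) <= {0, 1}
            disagree = np.mean((ai[:, :, 0] > 0.5).astype(int) != am)
            assert disagree < 0.05


class TestTrain:
    def test_loss_decreases_on_separable_task(self, texture_2class):
        _, images, labels = texture_2class
        cfg = TrainConfig(batch_size=8, learning_rate=0.05, max_epochs=5,
                          augmentation=False)
        m = tiny_cnn(2, n_act_layers=3, seed=0)
        tm = train(m, images, labels, cfg, seed=0)
        assert tm.loss_history[-1] < tm.loss_history[0]
        x = np.transpose(images, (0, 3, 1, 2))
        acc = accuracy(np.argmax(tm.predict_proba(x), axis=1), labels)
        assert acc > 0.9

    def test_zero_epochs_returns_identical_model(self, small_cnn, rng):
        images = rng.random((6, 16, 16, 3))
        labels = rng.integers(0, 3, 6)
        tm = train(small_cnn, images, labels,
                   TrainConfig(max_epochs=0), seed=0)
        x = rng.random((2, 3, 16, 16))
        np.testing.assert_array_equal(tm.predict_proba(x), small_cnn.predict_proba(x))

    def test_same_seed_same_weights(self, texture_2class):
        _, images, labels = texture_2class
        cfg = TrainConfig(batch_size=8, learning_rate=0.05, max_epochs=2,
                          augmentation=True, augment_epochs=2)
        m = tiny_cnn(2, n_act_layers=2, seed=0)
        t1 = train(m, images[:16], labels[:16], cfg, seed=9)
        t2 = train(m, images[:16], labels[:16], cfg, seed=9)
        assert t1.weight_hash() == t2.weight_hash()
        assert t1.loss_history == t2.loss_history

    def test_out_of_range_labels_rejected(self, small_cnn, rng):
        images = rng.random((4, 16, 16, 3))
        with pytest.raises(ValueError):
            train(small_cnn, images, np.array([0, 1, 2, 3]), TrainConfig(max_epochs=1))

    def test_segmentation_training_with_class_weights(self, rng):
        """Pixel-wise weighted cross-entropy trains the encoder-decoder."""
        from stochact import SynthSegSpec, gen_segmentation
        images, masks = gen_segmentation(SynthSegSpec(n_images=12, seed=4))
        m = tiny_segmenter(2, seed=0)
        cfg = TrainConfig.segmentation(batch_size=4, learning_rate=0.05,
                                       max_epochs=4, augmentation=False)
        tm = train(m, images, masks, cfg, seed=0)
        assert tm.loss_history[-1] < tm.loss_history[0]
        x = np.transpose(images, (0, 3, 1, 2))
        pred = np.argmax(tm.predict_proba(x), axis=1)
        f1 = pixel_f1(list(pred), list(masks))
        assert f1 > 0.6


class TestMetrics:
    def test_accuracy_counts(self):
        assert accuracy(np.array([1, 2, 3]), np.array([1, 2, 3])) == 1.0
        assert accuracy(np.array([0, 0]), np.array([1, 1])) == 0.0
        assert accuracy(np.array([1, 1, 1, 0]), np.array([1, 1, 1, 1])) == 0.75
        with pytest.raises(ValueError):
            accuracy(np.array([]), np.array([]))

    def test_pixel_f1_formula(self):
        # tp=2, fp=1, fn=1 -> 2*2/(2*2+1+1) = 2/3
        pred = np.array([[1, 1], [1, 0]])
        gt = np.array([[1, 1], [0, 1]])
        assert pixel_f1(pred, gt) == pytest.approx(4 / 6)

    def test_pixel_f1_edge_cases(self):
        gt = np.array([[1, 0], [0, 0]])
        assert pixel_f1(gt, gt) == 1.0
        assert pixel_f1(np.zeros((2, 2)), gt) == 0.0
        assert pixel_f1(np.zeros((2, 2)), np.zeros((2, 2))) == 1.0
        with pytest.raises(ValueError):
            pixel_f1(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_pixel_f1_aggregates_over_dataset(self):
        """Counts pool across images: differs from averaging per-image F1."""
        p1, g1 = np.array([[1, 1]]), np.array([[1, 1]])      # tp=2
        p2, g2 = np.array([[1, 0]]), np.array([[0, 1]])      # fp=1, fn=1
        pooled = pixel_f1([p1, p2], [g1, g2])
        assert pooled == pytest.approx(2 * 2 / (2 * 2 + 1 + 1))
        per_image_mean = (1.0 + 0.0) / 2
        assert pooled != pytest.approx(per_image_mean)


class TestWilcoxon:
    def test_identical_vectors_give_p_one(self):
        a = np.arange(6, dtype=float)
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank(a, a) == 1.0

    def test_two_sided_symmetry(self, rng):
        a = rng.random(9)
        b = rng.random(9)
        assert wilcoxon_signed_rank(a, b) == wilcoxon_signed_rank(b, a)

    def test_matches_brute_force_enumeration(self, rng):
        """Exact enumeration oracle over all 2^n sign assignments, n=8."""
        for trial in range(20):
            d = rng.normal(0, 1, 8)
            d[d == 0] = 0.5
            a = rng.random(8)
            b = a - d
            ranks = stats.rankdata(np.abs(d))
            w_obs = float(np.sum(ranks[d > 0]))
            total = float(np.sum(ranks))
            lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
            count = 0
            for signs in itertools.product([0, 1], repeat=8):
                w = float(np.sum(ranks[np.array(signs, dtype=bool)]))
                if w <= lo + 1e-9 or w >= hi - 1e-9:
                    count += 1
            expected = min(count / 2 ** 8, 1.0)
            assert wilcoxon_signed_rank(a, b) == pytest.approx(expected)

    def test_agrees_with_scipy_exact_when_tie_free(self, rng):
        for trial in range(10):
            d = rng.normal(0, 1, 10)
            a = rng.random(10)
            b = a - d
            ours = wilcoxon_signed_rank(a, b)
            ref = stats.wilcoxon(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [3, 4])


class TestResize:
    def test_identity_at_target_size(self, rng):
        img = rng.random((224, 224, 3))
        np.testing.assert_array_equal(resize_for_model(img), img)

    def test_constant_image_stays_constant(self):
        img = np.full((448, 448, 3), 0.25)
        out = resize_for_model(img)
        assert out.shape == (224, 224, 3)
        np.testing.assert_allclose(out, 0.25)

    def test_mask_round_trip_on_even_factors(self, rng):
        mask = (rng.random((100, 80)) > 0.5).astype(int)
        up = resize_mask_back(mask, (200, 160))
        back = resize_mask_back(up, (100, 80))
        np.testing.assert_array_equal(back, mask)
        assert set(np.unique(up)) <= {0, 1}

    def test_zero_target_rejected(self, rng):
        with pytest.raises(ValueError):
            resize_for_model(rng.random((4, 4, 3)), (0, 224))


def test_kfold_partitions_all_samples():
    labels = np.repeat([0, 1, 2], 10)
    folds = kfold_indices(labels, k=5, seed=0)
    assert len(folds) == 5
    all_test = np.concatenate([te for _, te in folds])
    assert sorted(all_test) == list(range(30))


def test_evaluation_report_ranks_by_average():
    scores = {
        "A": {"d1": 0.9, "d2": 0.8},
        "B": {"d1": 0.7, "d2": 0.6},
        "C": {"d1": 0.95, "d2": 0.85},
    }
    df = evaluation_report(scores)
    assert df.loc["C", "Rank"] == 1
    assert df.loc["A", "Rank"] == 2
    assert df.loc["B", "Rank"] == 3
    assert df.loc["A", "Avg"] == pytest.approx(0.85)


def test_pairwise_wilcoxon_matrix_symmetric():
    rng = np.random.default_rng(0)
    scores = {m: {f"d{i}": float(rng.random()) for i in range(8)} for m in "XYZ"}
    mat = pairwise_wilcoxon(scores)
    np.testing.assert_allclose(mat.values, mat.values.T)
    assert np.all(np.diag(mat.values) == 1.0)
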