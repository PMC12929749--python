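import numpy as np
import pytest

from rpeseg.classify import (REFERENCE_CONV_FILTERS, REFERENCE_DENSE_UNITS,
                             ClassifyTrainConfig, SliceScoreSeries,
                             build_classifier, classify_volume,
                             moving_average, train_classifier,
                             youden_threshold)
from rpeseg.planes import PlaneView


def _brute_force_youden(scores, labels):
    """Independent oracle: scan every candidate cutpoint exhaustively."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    uniq = np.unique(s)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2,
                            [uniq[-1] + 1]])
    best = -np.inf
    for t in cands:
        pred = s >= t
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        best = max(best, sens + spec - 1)
    return best


class TestArchitecture:
    def test_reference_parameter_count(self):
        model = build_classifier(seed=0)
        assert model.num_params() == 565_873

    def test_forward_returns_scalar_probability(self):
        model = build_classifier(seed=0, conv_filters=(2, 2, 2, 2),
                                 dense_units=(4, 4, 4))
        score = model.predict_scores(np.random.default_rng(0)
                                     .random((1, 128, 128)))
        assert score.shape == (1,)
        assert 0.0 < score[0] < 1.0

    def test_seeded_rebuild_is_identical(self):
        x = np.random.default_rng(1).random((2, 128, 128)).astype(np.float32)
        a = build_classifier(seed=9, conv_filters=(2, 2, 2, 2),
                             dense_units=(4, 4, 4)).predict_scores(x)
        b = build_classifier(seed=9, conv_filters=(2, 2, 2, 2),
                             dense_units=(4, 4, 4)).predict_scores(x)
        np.testing.assert_array_equal(a, b)


class TestMovingAverage:
    def test_window3_with_shrinking_edges(self):
        out = moving_average([1, 0, 0, 0, 1], window=3)
        np.testing.assert_allclose(out, [0.5, 1 / 3, 0, 1 / 3, 0.5])

    def test_window1_is_identity(self):
        s = np.random.default_rng(0).random(10)
        np.testing.assert_array_equal(moving_average(s, window=1), s)

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(moving_average(np.full(7, 0.3), 3), 0.3)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average([1, 2, 3], window=2)

    def test_linear_in_input(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(20), rng.random(20)
        np.testing.assert_allclose(
            moving_average(2 * a + 3 * b, 5),
            2 * moving_average(a, 5) + 3 * moving_average(b, 5))


class TestYoudenThreshold:
    def test_perfect_separation_midpoint(self):
        thr, j = youden_threshold([0.2, 0.3, 0.7, 0.9], [0, 0, 1, 1])
        assert thr == pytest.approx(0.5)
        assert j == pytest.approx(1.0)

    def test_tie_breaks_toward_lower_threshold(self):
        thr, j = youden_threshold([0.1, 0.6, 0.4, 0.9], [0, 0, 1, 1])
        assert thr == pytest.approx(0.25)
        assert j == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([0.1, 0.9], [1, 1])

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(4, 25))
            scores = np.round(rng.random(n), 2)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            thr, j = youden_threshold(scores, labels)
            assert j == pytest.approx(_brute_force_youden(scores, labels))
            # returned threshold actually achieves the returned J
            pred = scores >= thr
            sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            assert sens + spec - 1 == pytest.approx(j)


class TestTraining:
    @pytest.fixture(scope="class")
    def toy_data(self):
        """Separable 128×128 slices: bright center square vs background."""
        rng = np.random.default_rng(8)
        xs, ys = [], []
        for i in range(40):
            img = rng.normal(0.2, 0.05, (128, 128))
            label = i % 2
            if label:
                img[48:80, 48:80] += 0.5
            xs.append(np.clip(img, 0, 1))
            ys.append(label)
        return np.stack(xs).astype(np.float32), np.array(ys)

    def test_loss_decreases_on_separable_data(self, toy_data):
        x, y = toy_data
        model = build_classifier(seed=0, conv_filters=(2, 4, 4, 8),
                                 dense_units=(8, 8, 4))
        hist = train_classifier(model, x, y,
                                ClassifyTrainConfig(epochs=5, seed=0))
        assert hist[-1] < hist[0]

    def test_zero_epochs_is_noop(self, toy_data):
        x, y = toy_data
        model = build_classifier(seed=1, conv_filters=(2, 2, 2, 2),
                                 dense_units=(4, 4, 4))
        before = model.predict_scores(x[:4])
        train_classifier(model, x, y, ClassifyTrainConfig(epochs=0, seed=0))
        np.testing.assert_array_equal(before, model.predict_scores(x[:4]))

    def test_single_class_training_rejected(self, toy_data):
        x, _ = toy_data
        model = build_classifier(seed=1, conv_filters=(2, 2, 2, 2),
                                 dense_units=(4, 4, 4))
        with pytest.raises(ValueError):
            train_classifier(model, x, np.ones(len(x)),
                             ClassifyTrainConfig(epochs=1, seed=0))


class TestSeriesAndClassifyVolume:
    def test_labels_follow_threshold(self):
        series = SliceScoreSeries(view=PlaneView.AXIAL,
                                  raw=np.array([0.1, 0.6, 0.8]),
                                  smoothed=np.array([0.1, 0.6, 0.8]),
                                  threshold=0.6)
        np.testing.assert_array_equal(series.labels, [0, 1, 1])

    def test_series_length_and_threshold_monotonicity(self, easy_case):
        model = build_classifier(seed=0, conv_filters=(2, 2, 2, 2),
                                 dense_units=(4, 4, 4))
        lo = classify_volume(model, easy_case.volume, PlaneView.AXIAL, 0.2)
        hi = classify_volume(model, easy_case.volume, PlaneView.AXIAL, 0.8)
        assert len(lo.labels) == easy_case.volume.shape[0]
        # raising the threshold can only switch labels 1 -> 0
        assert np.all(hi.labels <= lo.labels)

    def test_view_mismatch_rejected(self, easy_case):
        model = build_classifier(seed=0, conv_filters=(2, 2, 2, 2),
                                 dense_units=(4, 4, 4), view=PlaneView.CORONAL)
        with pytest.raises(ValueError):
            classify_volume(model, easy_case.volume, PlaneView.AXIAL, 0.5)
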