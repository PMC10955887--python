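"""Normalization, GNB, framing, grid-search training, unified predict."""

import warnings

import numpy as np
import pytest

import hippodecode as hd
from hippodecode.decoders import _grid_candidates
from hippodecode.errors import InsufficientDataError, InvalidParameterError, ShapeError


class TestNormalizer:
    def test_training_columns_become_standard(self, rng):
        x = rng.normal(3.0, 2.0, size=(200, 5))
        norm = hd.fit_normalizer(x)
        z = norm.apply(x)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-12)

    def test_hand_computed_column(self):
        norm = hd.fit_normalizer(np.array([[1.0], [2.0], [3.0]]))
        z = norm.apply(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.ravel(), [-1.224744871, 0.0, 1.224744871], atol=1e-9)

    def test_already_standardized_is_identity(self, rng):
        x = rng.normal(size=(500, 3))
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        z = hd.fit_normalizer(x).apply(x)
        np.testing.assert_allclose(z, x, atol=1e-9)

    def test_constant_column_floors_and_warns(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning):
            norm = hd.fit_normalizer(x)
        z = norm.apply(x)
        np.testing.assert_allclose(z[:, 0], 0.0)

    def test_frozen_statistics_applied_to_new_data(self, rng):
        train = rng.normal(5, 2, size=(100, 2))
        norm = hd.fit_normalizer(train)
        new = rng.normal(5, 2, size=(50, 2))
        np.testing.assert_allclose(norm.apply(new), (new - norm.mean) / norm.sd)


class TestGnb:
    def brute_force_predict(self, model, x):
        """Literal evaluation: argmax_y P(y) prod_i Gaussian(x_i; mu, sigma)."""
        posts = []
        for ci in range(model.classes.size):
            likelihood = model.priors[ci]
            for fi in range(x.size):
                s = model.sigma[ci, fi]
                likelihood *= np.exp(-((x[fi] - model.mu[ci, fi]) ** 2) / (2 * s**2)) / np.sqrt(
                    2 * np.pi * s**2
                )
            posts.append(likelihood)
        posts = np.asarray(posts)
        return model.classes[int(np.argmax(posts))], posts / posts.sum()

    def test_parameter_recovery(self, rng):
        n = 400
        x = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(2, 1, (n, 3))])
        y = np.repeat([0, 1], n)
        model = hd.gnb_fit(x, y)
        se = 1.0 / np.sqrt(n)
        assert np.all(np.abs(model.mu[0] - 0) < 3 * se)
        assert np.all(np.abs(model.mu[1] - 2) < 3 * se)
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    def test_single_class(self):
        model = hd.gnb_fit(np.random.default_rng(0).normal(size=(5, 2)), np.zeros(5))
        label, post = hd.gnb_predict(model, np.zeros(2))
        assert label == 0
        assert post[0] == pytest.approx(1.0)

    def test_constant_feature_is_floored(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.repeat([0, 1], 5)
        model = hd.gnb_fit(x, y)
        _, post = hd.gnb_predict(model, np.array([1.0, 4.0]))
        assert np.all(np.isfinite(post))

    def test_tiny_class_raises(self):
        with pytest.raises(InsufficientDataError):
            hd.gnb_fit(np.zeros((3, 2)), np.array([0, 0, 1]))

    def test_symmetric_point_ties_to_lower_class(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 1, (500, 1)), rng.normal(2, 1, (500, 1))])
        y = np.repeat([0, 1], 500)
        model = hd.gnb_fit(x, y)
        # force exact symmetry
        model.mu[:] = [[0.0], [2.0]]
        model.sigma[:] = 1.0
        model.priors[:] = 0.5
        label, post = hd.gnb_predict(model, np.array([1.0]))
        np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-12)
        assert label == 0  # tie -> lowest class index
        label2, _ = hd.gnb_predict(model, np.array([0.9]))
        assert label2 == 0

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(20):
            x = rng.normal(size=(30, 4))
            y = rng.integers(0, 3, size=30)
            while np.unique(y).size < 3 or np.min(np.bincount(y)) < 2:
                y = rng.integers(0, 3, size=30)
            model = hd.gnb_fit(x, y)
            probe = rng.normal(size=4)
            label, post = hd.gnb_predict(model, probe)
            ref_label, ref_post = self.brute_force_predict(model, probe)
            assert label == ref_label
            np.testing.assert_allclose(post, ref_post, atol=1e-10)

    def test_nan_input_raises(self):
        model = hd.gnb_fit(np.random.default_rng(0).normal(size=(10, 2)), np.repeat([0, 1], 5))
        with pytest.raises(InvalidParameterError):
            hd.gnb_predict(model, np.array([np.nan, 0.0]))


class TestFraming:
    def test_window_count(self):
        traces = hd.TraceMatrix(np.zeros((2, 100)), np.arange(2), 30.0)
        windows, labels = hd.make_windows(traces, 5, np.arange(100))
        assert windows.shape == (96, 5, 2)
        assert labels[0] == 4  # label of the window's last frame

    def test_window_of_one_is_identity_framing(self):
        traces = hd.TraceMatrix(np.arange(10.0)[None], np.array([0]), 30.0)
        windows, labels = hd.make_windows(traces, 1, np.arange(10))
        assert windows.shape == (10, 1, 1)
        np.testing.assert_array_equal(windows[:, 0, 0], np.arange(10.0))

    def test_too_short_raises(self):
        traces = hd.TraceMatrix(np.zeros((1, 3)), np.array([0]), 30.0)
        with pytest.raises(InsufficientDataError):
            hd.make_windows(traces, 5, np.zeros(3))

    def test_epoch_extraction(self, auditory_session):
        traces, sched = auditory_session
        epochs = hd.make_epochs(traces, sched, e=150)
        assert epochs.n_epochs == 50
        assert epochs.epoch_frames == 150
        assert epochs.values.shape[1] == traces.n_neurons
        assert epochs.epoch_frames / traces.fps == pytest.approx(5.0)
        np.testing.assert_array_equal(epochs.labels, sched.epoch_labels())

    def test_trailing_incomplete_epoch_dropped(self, auditory_session):
        traces, sched = auditory_session
        onset = sched.epoch_onsets()[-1]
        short = hd.TraceMatrix(traces.values[:, : onset + 100], traces.neuron_ids, 30.0)
        short_sched = hd.StimulusSchedule(
            np.arange(onset + 100), sched.state[: onset + 100], 30.0, "auditory"
        )
        with pytest.warns(UserWarning, match="incomplete"):
            epochs = hd.make_epochs(short, short_sched, e=150)
        assert epochs.n_epochs == 49


class TestTrainDecoder:
    def separable(self, rng, n=150):
        x = np.vstack([rng.normal(0, 0.3, (n, 4)), rng.normal(3, 0.3, (n, 4))])
        y = np.repeat([0, 1], n)
        return x, y

    @pytest.mark.parametrize("kind", ["svm", "mlp"])
    def test_separable_classes_reach_high_cv_accuracy(self, kind, rng):
        x, y = self.separable(rng)
        grid = {"svm": {"C": [1.0]}, "mlp": {"hidden": [16], "lr": [1e-3], "epochs": [30]}}[kind]
        model = hd.train_decoder(kind, x, y, grid=grid, seed=0)
        best = max(r["mean_accuracy"] for r in model.cv_results)
        assert best > 0.98

    def test_shuffled_labels_decode_at_chance(self, rng):
        x = rng.normal(size=(300, 4))
        y = rng.integers(0, 3, size=300)
        model = hd.train_decoder("gnb", x, y, seed=0)
        acc = model.cv_results[0]["mean_accuracy"]
        assert abs(acc - 1 / 3) < 0.12

    def test_same_seed_selects_same_hyperparameters(self, rng):
        x, y = self.separable(rng, n=60)
        kwargs = dict(grid={"C": [0.1, 1.0, 10.0]}, seed=3)
        a = hd.train_decoder("svm", x, y, **kwargs)
        b = hd.train_decoder("svm", x, y, **kwargs)
        assert a.best_params == b.best_params
        assert a.cv_results == b.cv_results

    def test_unknown_kind_raises(self):
        with pytest.raises(InvalidParameterError):
            hd.train_decoder("forest", np.zeros((10, 2)), np.zeros(10))

    def test_class_below_fold_count_raises(self):
        x = np.zeros((7, 2))
        y = np.array([0, 0, 0, 0, 0, 1, 1])
        with pytest.raises(InsufficientDataError):
            hd.train_decoder("gnb", x, y, folds=5)

    def test_grid_scan_order_prefers_small_models(self):
        combos = _grid_candidates("mlp", {"hidden": [128, 32], "lr": [1e-3], "epochs": [20]})
        assert combos[0]["hidden"] == 32


class TestPredict:
    def test_gnb_path_delegates(self, rng):
        x = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(4, 1, (50, 3))])
        y = np.repeat([0, 1], 50)
        model = hd.train_decoder("gnb", x, y, seed=0)
        probe = rng.normal(size=3)
        label, scores = hd.predict(model, probe)
        ref_label, ref_scores = hd.gnb_predict(model.estimator, model.normalizer.apply(probe))
        assert label == ref_label
        np.testing.assert_allclose(scores, ref_scores)

    def test_mlp_memorizes_toy_training_point(self, rng):
        x = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(5, 0.1, (30, 2))])
        y = np.repeat(["a", "b"], 30)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = hd.train_decoder(
                "mlp", x, y, grid={"hidden": [16], "lr": [1e-2], "epochs": [100]}, seed=0
            )
        label, _ = hd.predict(model, x[0])
        assert label == "a"

    def test_cnn_on_zero_epoch_returns_valid_class(self, rng):
        x = rng.normal(size=(20, 20, 3))
        y = np.repeat(["4kHz", "8kHz"], 10)
        model = hd.train_decoder(
            "cnn", x, y, grid={"filters": [4], "lr": [1e-3], "epochs": [2]}, folds=2, seed=0
        )
        label, scores = hd.predict(model, np.zeros((20, 3)))
        assert label in model.classes
        assert scores.sum() == pytest.approx(1.0)

    def test_contract_violation_raises(self, rng):
        x = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(4, 1, (20, 3))])
        model = hd.train_decoder("gnb", x, np.repeat([0, 1], 20), seed=0)
        with pytest.raises(ShapeError):
            hd.predict(model, np.zeros((5, 5, 3)))

    def test_window_length_enforced(self, rng):
        x = rng.normal(size=(40, 5, 2))
        x[20:] += 2
        y = np.repeat([0, 1], 20)
        model = hd.train_decoder(
            "lstm", x, y, grid={"hidden": [8], "lr": [1e-2], "epochs": [3]}, folds=2, seed=0
        )
        with pytest.raises(ShapeError):
            hd.predict(model, np.zeros((3, 2)))
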