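"""Training/real-time session orchestration and error evaluation."""

import dataclasses

import numpy as np
import pytest

import hippodecode as hd
from hippodecode.errors import InsufficientDataError, InvalidParameterError, ShapeError

FAST_GRIDS = {
    "svm": {"C": [1.0]},
    "mlp": {"hidden": [32], "lr": [1e-3], "epochs": [20]},
    "lstm": {"hidden": [16], "lr": [1e-3], "epochs": [8]},
    "cnn": {"filters": [8], "lr": [1e-3], "epochs": [10]},
}


@pytest.fixture(scope="module")
def position_artifacts(behavior_12_trials, place_population):
    traces, _ = place_population
    config = hd.PipelineConfig(modality="position", n_shuffles=100, seed=1)
    return hd.run_training_session(
        traces, behavior_12_trials, config, decoder_kinds=("gnb", "mlp"), grids=FAST_GRIDS
    )


class TestTrainingSession:
    def test_artifacts_are_coherent(self, position_artifacts, place_population):
        art = position_artifacts
        traces, _ = place_population
        assert set(art.sensitive_ids.tolist()) <= set(traces.neuron_ids.tolist())
        # most tuned neurons detected, few untuned ones
        tuned_hits = np.sum(art.sensitive_ids < 60)
        untuned_hits = np.sum(art.sensitive_ids >= 60)
        assert tuned_hits >= 30
        assert untuned_hits <= 5
        assert art.best_kind in art.models
        assert art.kalman is not None
        assert set(art.holdout_errors) == {"gnb", "mlp"}

    def test_driver_shorter_than_traces_aborts(self, behavior_12_trials, place_population):
        traces, _ = place_population
        short = hd.BehaviorTrack(
            behavior_12_trials.frame_index[:-10],
            behavior_12_trials.position_cm[:-10],
            30.0,
            160.0,
        )
        with pytest.raises(ShapeError):
            hd.run_training_session(traces, short, hd.PipelineConfig(n_shuffles=10))

    def test_no_sensitive_neurons_aborts(self, behavior_12_trials):
        cells = hd.make_untuned_cells(5)
        traces, _ = hd.simulate_tuned_traces(cells, behavior=behavior_12_trials, seed=9)
        with pytest.raises(InsufficientDataError):
            hd.run_training_session(
                traces,
                behavior_12_trials,
                hd.PipelineConfig(modality="position", n_shuffles=50, percentile=99.9, seed=0),
            )

    def test_visual_session_decodes_well(self, visual_session):
        traces, sched = visual_session
        config = hd.PipelineConfig(modality="visual", n_shuffles=100, seed=2)
        art = hd.run_training_session(
            traces, sched, config, decoder_kinds=("gnb",), grids=FAST_GRIDS
        )
        assert art.holdout_errors["gnb"] < 20.0  # % frame error; chance is 50%
        assert art.maps.raw.shape[0] == art.sensitive_ids.size

    def test_sensitive_fraction_helper(self, position_artifacts):
        all_ids = hd.top_sensitive_ids(position_artifacts.tuning_results, 1.0)
        half_ids = hd.top_sensitive_ids(position_artifacts.tuning_results, 0.5)
        assert half_ids.size == max(1, round(all_ids.size * 0.5))
        assert set(half_ids.tolist()) <= set(all_ids.tolist())


class TestRealtimeSession:
    def test_streaming_equals_offline(self, position_artifacts, place_population):
        traces, _ = place_population
        result = hd.run_realtime_session(traces, position_artifacts)
        _, offline = hd.decode_offline(position_artifacts, traces)
        np.testing.assert_array_equal(result.predicted, offline)

    def test_streaming_equals_offline_lstm(self, behavior_12_trials, place_population):
        traces, _ = place_population
        config = hd.PipelineConfig(modality="position", n_shuffles=50, seed=3)
        art = hd.run_training_session(
            traces, behavior_12_trials, config, decoder_kinds=("lstm",), grids=FAST_GRIDS
        )
        result = hd.run_realtime_session(traces, art)
        frames, offline = hd.decode_offline(art, traces)
        assert result.warmup_frames == config.lstm_window - 1
        np.testing.assert_array_equal(result.frame_index, frames)
        np.testing.assert_array_equal(result.predicted, offline)

    def test_auditory_stream_emits_one_prediction_per_epoch(self, auditory_session):
        traces, sched = auditory_session
        config = hd.PipelineConfig(modality="auditory", n_shuffles=50, seed=4)
        art = hd.run_training_session(
            traces, sched, config, decoder_kinds=("cnn",), grids=FAST_GRIDS
        )
        result = hd.run_realtime_session(traces, art, schedule=sched)
        assert result.granularity == "epoch"
        assert result.predicted.size == 50
        # frozen-model check: epoch decoding error well below chance (66.7%)
        truth = sched.epoch_labels()
        err = 100 * np.mean(result.predicted != truth)
        assert err < 40.0

    def test_kalman_output_stays_on_track(self, position_artifacts, place_population):
        traces, _ = place_population
        result = hd.run_realtime_session(traces, position_artifacts)
        assert result.filtered_position_cm is not None
        assert result.filtered_position_cm.min() >= 0
        assert result.filtered_position_cm.max() <= 160
        assert all(np.all(v >= 0) for v in result.latency_ms.values())

    def test_neuron_set_mismatch_aborts(self, position_artifacts):
        wrong = hd.TraceMatrix(np.zeros((3, 100)), np.array([900, 901, 902]), 30.0)
        with pytest.raises(InvalidParameterError):
            hd.run_realtime_session(wrong, position_artifacts)


class TestEvaluateDecoding:
    def make_result(self, predicted, positions=None, modality="visual"):
        n = len(predicted)
        return hd.StreamResult(
            modality=modality,
            granularity="frame",
            frame_index=np.arange(n),
            predicted=np.asarray(predicted, dtype=object if modality != "position" else np.int64),
            raw_position_cm=positions,
            filtered_position_cm=positions,
            latency_ms={},
            over_budget=np.zeros(n, bool),
            warmup_frames=0,
        )

    def test_perfect_predictions_score_zero(self):
        result = self.make_result(["light", "dark"] * 10)
        report = hd.evaluate_decoding(result, np.array(["light", "dark"] * 10, dtype=object))
        assert report.error_rate_pct == 0.0
        assert np.trace(report.confusion) == 20

    def test_constant_offset_position_error(self):
        truth = np.linspace(10, 100, 50)
        pred_pos = truth + 4.0
        result = self.make_result(np.zeros(50, int), positions=pred_pos, modality="position")
        report = hd.evaluate_decoding(result, truth)
        assert report.mean_error == pytest.approx(4.0)
        assert report.median_error == pytest.approx(4.0)

    def test_random_three_class_predictions_near_chance(self, rng):
        classes = np.array(["4kHz", "8kHz", "16kHz"], dtype=object)
        pred = classes[rng.integers(0, 3, 3000)]
        truth = classes[rng.integers(0, 3, 3000)]
        report = hd.evaluate_decoding(self.make_result(pred), truth)
        assert report.error_rate_pct == pytest.approx(66.7, abs=5.0)

    def test_cumulative_fraction_monotone_zero_to_one(self, rng):
        truth = rng.uniform(0, 160, 200)
        pred_pos = truth + rng.normal(0, 5, 200)
        result = self.make_result(np.zeros(200, int), positions=pred_pos, modality="position")
        report = hd.evaluate_decoding(result, truth)
        curve = report.cumulative_fraction
        assert np.all(np.diff(curve) >= 0)
        assert curve[-1] == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        result = self.make_result(["light"] * 5)
        with pytest.raises(ShapeError):
            hd.evaluate_decoding(result, np.array(["light"] * 4, dtype=object))
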