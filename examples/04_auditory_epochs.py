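"""Epoch-wise decoding of tone frequency with the temporal CNN.

Tones (4/8/16 kHz, 2 s on + 3 s mute) evoke latency-jittered, long-lasting
responses, so single frames decode poorly; instead each 5 s epoch
(150 frames at 30 fps) is classified as a whole.
"""

import hippodecode as hd

config = hd.PipelineConfig(modality="auditory", n_shuffles=200, seed=6)
train_sched = hd.simulate_stimulus_schedule("auditory", 30, n_stimuli=60, seed=6)
rt_sched = hd.simulate_stimulus_schedule("auditory", 30, n_stimuli=20, seed=7)
cells = hd.make_auditory_cells(60) + hd.make_untuned_cells(15, start_id=60)
train_traces, _ = hd.simulate_tuned_traces(cells, schedule=train_sched, seed=8)
rt_traces, _ = hd.simulate_tuned_traces(cells, schedule=rt_sched, seed=9)

artifacts = hd.run_training_session(
    train_traces, train_sched, config,
    grids={"cnn": {"filters": [8], "lr": [1e-3], "epochs": [10]}},
)
print(f"sensitive neurons: {artifacts.sensitive_ids.size}/75")
print(f"holdout epoch error (cnn): {artifacts.holdout_errors['cnn']:.2f}%")

result = hd.run_realtime_session(rt_traces, artifacts, schedule=rt_sched)
truth = rt_sched.epoch_labels()[: result.predicted.size]
report = hd.evaluate_decoding(result, truth)
print(f"streamed epochs: {result.predicted.size}, error {report.error_rate_pct:.2f}% "
      f"(chance 66.7%)")
# One prediction per tone onset: the stream buffers 150 frames from each
# known onset, then classifies the epoch.
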