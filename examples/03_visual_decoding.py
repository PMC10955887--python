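"""Frame-by-frame decoding of a light/dark visual stimulus.

Light is on 2 s / off 2 s; every frame is classified from the population
vector of sensitive neurons.
"""

import numpy as np

import hippodecode as hd

config = hd.PipelineConfig(modality="visual", n_shuffles=200, seed=4)
schedule = hd.simulate_stimulus_schedule("visual", fps=30, n_stimuli=60, seed=4)
cells = hd.make_visual_cells(60) + hd.make_untuned_cells(15, start_id=60)
traces, _ = hd.simulate_tuned_traces(cells, schedule=schedule, seed=5)

artifacts = hd.run_training_session(
    traces, schedule, config, decoder_kinds=("gnb", "svm"),
    grids={"svm": {"C": [1.0]}},
)
print(f"sensitive neurons: {artifacts.sensitive_ids.size}/75")
print(f"holdout frame error: " +
      ", ".join(f"{k} {v:.2f}%" for k, v in artifacts.holdout_errors.items()))

result = hd.run_realtime_session(traces, artifacts)
truth = np.asarray(schedule.state, dtype=object)[result.frame_index]
report = hd.evaluate_decoding(result, truth)
print(f"streamed frame error ({artifacts.best_kind}): {report.error_rate_pct:.2f}% "
      f"(chance 50%)")
# Residual errors sit on the handful of frames right after each light/dark
# transition, before the evoked calcium transient has risen.
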