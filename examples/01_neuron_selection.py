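"""Select place-sensitive neurons with the information-content shuffle test.

Simulates a 12-trial linear-track session for a small mixed population,
scores each neuron's spatial information content, and runs the 95th
percentile shuffle test (200 shuffles here; 1000 is the full setting).
"""

import numpy as np

import hippodecode as hd

behavior = hd.simulate_track_behavior(0, fps=30, track_length_cm=160, n_trials=12, seed=1)
cells = hd.make_place_cells(30) + hd.make_untuned_cells(10, start_id=30)
traces, _ = hd.simulate_tuned_traces(cells, behavior=behavior, seed=2)

binning = hd.bin_occupancy(behavior, bin_cm=2.0)
results = hd.population_shuffle_test(traces, binning, n_shuffles=200, seed=3)

tuned = [r for r in results if r.neuron_id < 30]
untuned = [r for r in results if r.neuron_id >= 30]
print(f"session: {behavior.n_frames} frames, {binning.k} spatial bins")
print(f"place cells flagged sensitive : {sum(r.sensitive for r in tuned)}/30")
print(f"untuned cells flagged sensitive: {sum(r.sensitive for r in untuned)}/10")
print(f"mean information content: tuned {np.mean([r.i_obs for r in tuned]):.3f} bits, "
      f"untuned {np.mean([r.i_obs for r in untuned]):.3f} bits")
# Sensitive = observed information content strictly above the 95th
# percentile of the neuron's own shuffle null; tuned cells should clear it,
# untuned cells should be flagged at roughly the 5% false-positive rate.
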