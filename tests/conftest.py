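import numpy as np
import pytest

import hippodecode as hd


@pytest.fixture(scope="session")
def behavior_12_trials() -> hd.BehaviorTrack:
    """A 12-trial linear-track session at the default generator settings."""
    return hd.simulate_track_behavior(0, 30, 160, n_trials=12, seed=11)


@pytest.fixture(scope="session")
def spatial_binning(behavior_12_trials) -> "hd.OccupancyBinning":
    return hd.bin_occupancy(behavior_12_trials, 2.0)


@pytest.fixture(scope="session")
def place_population(behavior_12_trials):
    """60 place cells + 20 untuned neurons driven by the 12-trial session."""
    cells = hd.make_place_cells(60) + hd.make_untuned_cells(20, start_id=60)
    traces, tuning = hd.simulate_tuned_traces(cells, behavior=behavior_12_trials, seed=21)
    return traces, tuning


@pytest.fixture(scope="session")
def visual_session():
    """40-stimulus light/dark session with 40 tuned + 10 untuned neurons."""
    schedule = hd.simulate_stimulus_schedule("visual", 30, 40, seed=31)
    cells = hd.make_visual_cells(40) + hd.make_untuned_cells(10, start_id=40)
    traces, _ = hd.simulate_tuned_traces(cells, schedule=schedule, seed=32)
    return traces, schedule


@pytest.fixture(scope="session")
def auditory_session():
    """50-tone session with 42 tuned + 10 untuned neurons."""
    schedule = hd.simulate_stimulus_schedule("auditory", 30, 50, seed=41)
    cells = hd.make_auditory_cells(42) + hd.make_untuned_cells(10, start_id=42)
    traces, _ = hd.simulate_tuned_traces(cells, schedule=schedule, seed=42)
    return traces, schedule


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
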