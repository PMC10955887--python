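"""Synthetic data generator.

Everything downstream of raw acquisition can be exercised on data from this
module: linear-track behavior, visual and auditory stimulus schedules,
calcium traces from place-, light- and tone-tuned neurons with slow
indicator kinetics and additive noise, and optionally a rendered movie with
per-frame rigid drift for testing registration and trace extraction.

The generative model for a trace is deliberately simple: a per-frame event
probability derived from the neuron's tuning (rate x frame interval,
clipped to [0, 1]), a binary event train drawn from it, convolution with a
difference-of-exponentials calcium kernel, and i.i.d. Gaussian noise.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import (
    AUDITORY_OFF,
    AUDITORY_STATES,
    BehaviorTrack,
    CalciumKernel,
    FrameStack,
    GroundTruthTuning,
    NeuronFootprint,
    StimulusSchedule,
    TraceMatrix,
)
from .errors import InvalidParameterError

__all__ = [
    "simulate_track_behavior",
    "simulate_stimulus_schedule",
    "simulate_tuned_traces",
    "render_movie",
    "make_place_cells",
    "make_visual_cells",
    "make_auditory_cells",
    "make_untuned_cells",
]

# Behavior-model constants: speed jitter as a fraction of mean speed,
# the range of the random pause at each track end, and the speed
# resampling step.  Variable pauses keep the traversal sequence aperiodic,
# which circular-shift null distributions rely on.
SPEED_JITTER_FRAC = 0.2
PAUSE_RANGE_S = (0.5, 3.0)
SPEED_SEGMENT_S = 0.5

# Visual evoked-response constants: sensory responses are time-locked to
# the stimulus transition, so preferred-state onsets add a brief
# high-rate transient on top of the sustained state gain.
VISUAL_ONSET_RATE = 20.0  # events/s during the transient
VISUAL_ONSET_LATENCY_S = 0.05
VISUAL_ONSET_DURATION_S = 0.15


def simulate_track_behavior(
    duration_s: float,
    fps: float = 30.0,
    track_length_cm: float = 160.0,
    mean_speed_cm_s: float = 15.0,
    n_trials: int = 0,
    seed: int = 0,
) -> BehaviorTrack:
    """Back-and-forth traversals of a linear track.

    The animal runs end to end with piecewise-constant speed (resampled
    every 0.5 s with Gaussian jitter, sd = 20% of the mean) and pauses a
    random 0.5-3 s at each end before reversing.  Simulation continues
    until both ``duration_s`` of data exist and ``n_trials`` complete
    end-to-end traversals have occurred.
    """
    if fps <= 0:
        raise InvalidParameterError(f"fps must be > 0, got {fps}")
    if track_length_cm <= 0:
        raise InvalidParameterError(f"track_length_cm must be > 0, got {track_length_cm}")
    if duration_s < 0:
        raise InvalidParameterError(f"duration_s must be >= 0, got {duration_s}")
    if mean_speed_cm_s <= 0:
        raise InvalidParameterError(f"mean_speed_cm_s must be > 0, got {mean_speed_cm_s}")

    rng = np.random.default_rng(seed)
    dt = 1.0 / fps
    min_frames = int(round(duration_s * fps))
    seg_frames = max(1, int(round(SPEED_SEGMENT_S * fps)))

    positions: list[float] = []
    pos = 0.0
    direction = 1.0
    trials_done = 0

    def done() -> bool:
        return len(positions) >= min_frames and trials_done >= n_trials

    if min_frames == 0 and n_trials == 0:
        return BehaviorTrack(np.array([], dtype=np.int64), np.array([]), fps, track_length_cm)

    # safety cap so degenerate parameters cannot spin forever
    hard_cap = int(1e7)
    speed = mean_speed_cm_s
    frames_in_seg = 0
    while not done() and len(positions) < hard_cap:
        if frames_in_seg % seg_frames == 0:
            speed = mean_speed_cm_s * (1.0 + SPEED_JITTER_FRAC * rng.standard_normal())
            speed = max(speed, 0.2 * mean_speed_cm_s)
        pos += direction * speed * dt
        frames_in_seg += 1
        if (direction > 0 and pos >= track_length_cm) or (direction < 0 and pos <= 0.0):
            pos = track_length_cm if direction > 0 else 0.0
            trials_done += 1
            positions.append(pos)
            pause_frames = int(round(rng.uniform(*PAUSE_RANGE_S) * fps))
            for _ in range(pause_frames):
                if len(positions) >= hard_cap:
                    break
                positions.append(pos)
            direction *= -1.0
            frames_in_seg = 0
        else:
            positions.append(pos)

    arr = np.asarray(positions, dtype=np.float64)
    arr = np.clip(arr, 0.0, track_length_cm)
    return BehaviorTrack(np.arange(arr.size, dtype=np.int64), arr, fps, track_length_cm)


def simulate_stimulus_schedule(
    modality: str,
    fps: float = 30.0,
    n_stimuli: int = 150,
    seed: int = 0,
) -> StimulusSchedule:
    """Stimulus schedule as delivered by the rig.

    visual
        ``n_stimuli`` alternating light/dark blocks of 2 s each
        (one on-block + one off-block per stimulus; 4 s per cycle).
    auditory
        ``n_stimuli`` epochs of a uniformly random tone (4, 8 or 16 kHz)
        played for 2 s followed by 3 s of silence (5 s per epoch).
    """
    if modality not in ("visual", "auditory"):
        raise InvalidParameterError(f"unknown modality {modality!r}")
    if fps <= 0:
        raise InvalidParameterError(f"fps must be > 0, got {fps}")
    if n_stimuli < 0:
        raise InvalidParameterError(f"n_stimuli must be >= 0, got {n_stimuli}")

    rng = np.random.default_rng(seed)
    on_frames = int(round(2.0 * fps))
    states: list[str] = []
    if modality == "visual":
        off_frames = int(round(2.0 * fps))
        for _ in range(n_stimuli):
            states.extend(["light"] * on_frames)
            states.extend(["dark"] * off_frames)
    else:
        off_frames = int(round(3.0 * fps))
        tones = rng.integers(0, len(AUDITORY_STATES), size=n_stimuli)
        for k in tones:
            states.extend([AUDITORY_STATES[k]] * on_frames)
            states.extend([AUDITORY_OFF] * off_frames)
    arr = np.asarray(states, dtype=object)
    return StimulusSchedule(np.arange(arr.size, dtype=np.int64), arr, fps, modality)


def _instantaneous_rates(
    tuning: Sequence[GroundTruthTuning],
    behavior: BehaviorTrack | None,
    schedule: StimulusSchedule | None,
    fps: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-neuron per-frame event rate (events/s), N x T."""
    if behavior is not None:
        n_frames = behavior.n_frames
    else:
        n_frames = schedule.n_frames  # type: ignore[union-attr]
    rates = np.zeros((len(tuning), n_frames))
    if schedule is not None:
        onsets = schedule.epoch_onsets()
        onset_labels = schedule.epoch_labels()
    for row, tun in enumerate(tuning):
        rate = np.full(n_frames, tun.baseline_rate, dtype=np.float64)
        if tun.modality == "place":
            if behavior is None:
                raise InvalidParameterError(
                    f"neuron {tun.neuron_id} is place-tuned but no behavior was given"
                )
            d = behavior.position_cm - tun.field_center_cm
            rate += tun.gain * np.exp(-0.5 * (d / tun.field_width_cm) ** 2)
        elif tun.modality == "visual":
            if schedule is None or schedule.modality != "visual":
                raise InvalidParameterError(
                    f"neuron {tun.neuron_id} is visual-tuned but no visual schedule was given"
                )
            for state, g in tun.state_gains.items():
                active = schedule.state == state
                rate[active] += tun.gain * g
                # evoked responses are onset-locked: a brief high-rate
                # transient right after the preferred state begins, on top
                # of the sustained gain
                prev = np.concatenate(([False], active[:-1]))
                for onset in np.flatnonzero(active & ~prev):
                    a = onset + int(round(VISUAL_ONSET_LATENCY_S * fps))
                    b = min(n_frames, a + int(round(VISUAL_ONSET_DURATION_S * fps)))
                    rate[a:b] += VISUAL_ONSET_RATE * g
        elif tun.modality == "auditory":
            if schedule is None or schedule.modality != "auditory":
                raise InvalidParameterError(
                    f"neuron {tun.neuron_id} is tone-tuned but no auditory schedule was given"
                )
            # latency-jittered, variably long transient after each preferred onset
            for onset, label in zip(onsets, onset_labels):
                g = tun.state_gains.get(label, 0.0)
                if g == 0.0:
                    continue
                latency = (
                    tun.response_latency_s
                    if tun.response_latency_s is not None
                    else rng.uniform(0.0, 0.5)
                )
                duration = (
                    tun.response_duration_s
                    if tun.response_duration_s is not None
                    else rng.uniform(1.0, 3.0)
                )
                a = int(onset + round(latency * fps))
                b = min(n_frames, int(a + round(duration * fps)))
                rate[a:b] += tun.gain * g
        rates[row] = rate
    return rates


def simulate_tuned_traces(
    tuning: Sequence[GroundTruthTuning],
    behavior: BehaviorTrack | None = None,
    schedule: StimulusSchedule | None = None,
    kernel: CalciumKernel | None = None,
    noise_sd: float = 0.1,
    fps: float = 30.0,
    seed: int = 0,
) -> tuple[TraceMatrix, list[GroundTruthTuning]]:
    """Calcium traces for a population with known ground-truth tuning.

    Each neuron's per-frame event probability is rate/fps (clipped to 1);
    the binary event train is convolved with ``kernel`` and Gaussian noise
    of sd ``noise_sd`` (in units of the kernel amplitude) is added.
    """
    if behavior is None and schedule is None:
        raise InvalidParameterError("at least one of behavior/schedule is required")
    if behavior is not None and schedule is not None and behavior.n_frames != schedule.n_frames:
        raise InvalidParameterError("behavior and schedule must cover the same frames")
    kernel = kernel or CalciumKernel()
    rng = np.random.default_rng(seed)

    rates = _instantaneous_rates(tuning, behavior, schedule, fps, rng)
    n, t = rates.shape
    p = np.clip(rates / fps, 0.0, 1.0)
    events = rng.random((n, t)) < p
    k = kernel.evaluate(fps)
    traces = np.empty((n, t))
    for row in range(n):
        traces[row] = np.convolve(events[row].astype(np.float64), k)[:t]
    if noise_sd > 0:
        traces += noise_sd * kernel.amplitude * rng.standard_normal((n, t))
    ids = np.asarray([tun.neuron_id for tun in tuning])
    return TraceMatrix(traces, ids, fps), list(tuning)


def render_movie(
    footprints: Sequence[NeuronFootprint],
    traces: TraceMatrix,
    frame_shape: tuple[int, int],
    drift: np.ndarray | None = None,
    background: float = 100.0,
    spot_sigma_px: float = 1.5,
    spot_gain: float = 50.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> FrameStack:
    """Render traces into a movie: background + Gaussian spots + pixel noise.

    ``drift`` is a T x 2 array of per-frame (dy, dx) translations applied to
    every spot; all footprints must remain >= 1 px inside the frame at the
    maximal drift so the 3 x 3 extraction patch exists.
    """
    h, w = frame_shape
    t = traces.n_frames
    if len(footprints) != traces.n_neurons:
        raise InvalidParameterError("one footprint per trace row is required")
    if drift is None:
        drift = np.zeros((t, 2))
    drift = np.asarray(drift, dtype=np.float64)
    if drift.shape != (t, 2):
        raise InvalidParameterError(f"drift must be {t} x 2, got {drift.shape}")

    max_dy = float(np.max(np.abs(drift[:, 0]))) if t else 0.0
    max_dx = float(np.max(np.abs(drift[:, 1]))) if t else 0.0
    for fp in footprints:
        r, c = fp.centroid_row, fp.centroid_col
        if not (1 + max_dy <= r <= h - 2 - max_dy and 1 + max_dx <= c <= w - 2 - max_dx):
            raise InvalidParameterError(
                f"footprint {fp.neuron_id} at ({r}, {c}) leaves the frame under drift"
            )

    rng = np.random.default_rng(seed)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    frames = np.full((t, h, w), background, dtype=np.float64)
    inv2s2 = 1.0 / (2.0 * spot_sigma_px**2)
    for ti in range(t):
        dy, dx = drift[ti]
        for fi, fp in enumerate(footprints):
            cy, cx = fp.centroid_row + dy, fp.centroid_col + dx
            spot = np.exp(-((rows - cy) ** 2 + (cols - cx) ** 2) * inv2s2)
            frames[ti] += spot_gain * traces.values[fi, ti] * spot
    if noise_sd > 0:
        frames += noise_sd * rng.standard_normal(frames.shape)
    np.clip(frames, 0.0, None, out=frames)
    return FrameStack(frames, traces.fps)


# ---------------------------------------------------------------------------
# population factories

def make_place_cells(
    n: int,
    track_length_cm: float = 160.0,
    field_width_cm: float = 10.0,
    baseline_rate: float = 0.1,
    gain: float = 2.0,
    start_id: int = 0,
) -> list[GroundTruthTuning]:
    """``n`` place cells with field centers evenly spaced along the track."""
    centers = np.linspace(0.0, track_length_cm, n, endpoint=False) + track_length_cm / (2 * n)
    return [
        GroundTruthTuning(
            neuron_id=start_id + i,
            modality="place",
            baseline_rate=baseline_rate,
            gain=gain,
            field_center_cm=float(c),
            field_width_cm=field_width_cm,
        )
        for i, c in enumerate(centers)
    ]


def make_visual_cells(
    n: int,
    baseline_rate: float = 0.1,
    gain: float = 2.0,
    start_id: int = 0,
    seed: int = 0,
) -> list[GroundTruthTuning]:
    """Light- or dark-preferring cells (preference alternates deterministically)."""
    cells = []
    for i in range(n):
        pref = "light" if i % 2 == 0 else "dark"
        cells.append(
            GroundTruthTuning(
                neuron_id=start_id + i,
                modality="visual",
                baseline_rate=baseline_rate,
                gain=gain,
                state_gains={pref: 1.0},
            )
        )
    return cells


def make_auditory_cells(
    n: int,
    baseline_rate: float = 0.1,
    gain: float = 2.0,
    start_id: int = 0,
) -> list[GroundTruthTuning]:
    """Tone-frequency-preferring cells (preferred frequency cycles 4/8/16 kHz)."""
    return [
        GroundTruthTuning(
            neuron_id=start_id + i,
            modality="auditory",
            baseline_rate=baseline_rate,
            gain=gain,
            state_gains={AUDITORY_STATES[i % 3]: 1.0},
        )
        for i in range(n)
    ]


def make_untuned_cells(
    n: int, baseline_rate: float = 0.1, start_id: int = 0
) -> list[GroundTruthTuning]:
    """Baseline-only neurons for null-distribution and type-I-error tests."""
    return [
        GroundTruthTuning(neuron_id=start_id + i, modality="none", baseline_rate=baseline_rate)
        for i in range(n)
    ]
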