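"""Core data containers shared across the pipeline.

These are thin, validated wrappers around NumPy arrays: a behavior track
(per-frame position on the linear track), a stimulus schedule (per-frame
categorical state), a trace matrix (neurons x frames raw fluorescence), a
frame stack (movie), neuron footprints, and the synthetic ground-truth
tuning description used for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError, ShapeError

VISUAL_STATES = ("light", "dark")
AUDITORY_STATES = ("4kHz", "8kHz", "16kHz")
AUDITORY_OFF = "off"


@dataclasses.dataclass
class BehaviorTrack:
    """Per-frame animal position (cm) on a linear track sampled at ``fps``."""

    frame_index: np.ndarray
    position_cm: np.ndarray
    fps: float
    track_length_cm: float

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.position_cm = np.asarray(self.position_cm, dtype=np.float64)
        if self.frame_index.shape != self.position_cm.shape:
            raise ShapeError("frame_index and position_cm must have equal length")
        if self.fps <= 0:
            raise InvalidParameterError(f"fps must be > 0, got {self.fps}")
        if self.track_length_cm <= 0:
            raise InvalidParameterError("track_length_cm must be > 0")
        if self.frame_index.size and np.any(np.diff(self.frame_index) <= 0):
            raise InvalidParameterError("frame_index must be strictly increasing")
        if self.position_cm.size and (
            self.position_cm.min() < 0 or self.position_cm.max() > self.track_length_cm
        ):
            raise InvalidParameterError("positions must lie in [0, track_length_cm]")

    @property
    def time_s(self) -> np.ndarray:
        return self.frame_index / self.fps

    @property
    def n_frames(self) -> int:
        return self.frame_index.size


@dataclasses.dataclass
class StimulusSchedule:
    """Per-frame categorical stimulus state (one state per frame)."""

    frame_index: np.ndarray
    state: np.ndarray
    fps: float
    modality: str  # {"visual", "auditory"}

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.state = np.asarray(self.state, dtype=object)
        if self.frame_index.shape != self.state.shape:
            raise ShapeError("frame_index and state must have equal length")
        if self.modality not in ("visual", "auditory"):
            raise InvalidParameterError(
                f"modality must be 'visual' or 'auditory', got {self.modality!r}"
            )
        if self.fps <= 0:
            raise InvalidParameterError(f"fps must be > 0, got {self.fps}")
        alphabet = set(VISUAL_STATES if self.modality == "visual" else AUDITORY_STATES + (AUDITORY_OFF,))
        seen = set(self.state.tolist())
        if not seen <= alphabet:
            raise InvalidParameterError(
                f"states {sorted(seen - alphabet)} outside the {self.modality} alphabet"
            )

    @property
    def n_frames(self) -> int:
        return self.frame_index.size

    def epoch_onsets(self) -> np.ndarray:
        """Frame indices where a stimulus block starts.

        Visual: every transition into ``light`` (including frame 0 if light).
        Auditory: every transition from ``off`` (or start) into a tone state.
        """
        s = self.state
        if s.size == 0:
            return np.array([], dtype=np.int64)
        if self.modality == "visual":
            active = s == "light"
        else:
            active = s != AUDITORY_OFF
        prev = np.concatenate(([False], active[:-1]))
        return self.frame_index[active & ~prev]

    def epoch_labels(self) -> np.ndarray:
        """State label at each epoch onset."""
        onsets = self.epoch_onsets()
        pos = np.searchsorted(self.frame_index, onsets)
        return self.state[pos]


@dataclasses.dataclass
class TraceMatrix:
    """Raw fluorescence, neurons x frames."""

    values: np.ndarray
    neuron_ids: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError(f"values must be 2-D (neurons x frames), got ndim={self.values.ndim}")
        self.neuron_ids = np.asarray(self.neuron_ids)
        if self.neuron_ids.shape[0] != self.values.shape[0]:
            raise ShapeError("neuron_ids length must match number of trace rows")
        if self.fps <= 0:
            raise InvalidParameterError(f"fps must be > 0, got {self.fps}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("trace values must be finite")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def subset(self, neuron_ids: Sequence) -> "TraceMatrix":
        """Rows for the given neuron ids, in the given order."""
        index = {nid: i for i, nid in enumerate(self.neuron_ids.tolist())}
        try:
            rows = [index[nid] for nid in neuron_ids]
        except KeyError as exc:
            raise InvalidParameterError(f"unknown neuron id {exc.args[0]!r}") from exc
        return TraceMatrix(self.values[rows], np.asarray(list(neuron_ids)), self.fps)


@dataclasses.dataclass
class FrameStack:
    """Movie of T frames, H x W non-negative intensities, at ``fps``."""

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ShapeError(f"frames must be T x H x W, got ndim={self.frames.ndim}")
        if self.fps <= 0:
            raise InvalidParameterError(f"fps must be > 0, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclasses.dataclass(frozen=True)
class NeuronFootprint:
    """Integer centroid of a detected neuron; activity is read from the
    3 x 3 pixel patch around the centroid, so it must sit at least one pixel
    inside every border of the movie."""

    neuron_id: int
    centroid_row: int
    centroid_col: int

    def validate_for(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        r, c = self.centroid_row, self.centroid_col
        if not (1 <= r <= h - 2 and 1 <= c <= w - 2):
            raise InvalidParameterError(
                f"footprint for neuron {self.neuron_id} at ({r}, {c}) does not leave a "
                f"3x3 patch inside a {h}x{w} frame"
            )


@dataclasses.dataclass(frozen=True)
class CalciumKernel:
    """Difference-of-exponentials calcium impulse response.

    Defaults model a fast indicator: 0.05 s rise, 0.5 s decay.
    """

    rise_time_s: float = 0.05
    decay_time_s: float = 0.5
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.rise_time_s <= 0 or self.decay_time_s <= 0:
            raise InvalidParameterError("kernel time constants must be > 0")
        if self.rise_time_s >= self.decay_time_s:
            raise InvalidParameterError("rise_time_s must be < decay_time_s")

    def evaluate(self, fps: float, duration_s: float = 4.0) -> np.ndarray:
        """Sampled kernel, peak-normalized to ``amplitude``."""
        t = np.arange(0.0, duration_s, 1.0 / fps)
        k = np.exp(-t / self.decay_time_s) - np.exp(-t / self.rise_time_s)
        peak = k.max()
        if peak > 0:
            k = k / peak * self.amplitude
        return k


@dataclasses.dataclass(frozen=True)
class GroundTruthTuning:
    """Simulation ground truth for one synthetic neuron.

    modality: 'place' (Gaussian field over position), 'visual' (per-state
    gain), 'auditory' (latency-jittered transient after tone onset), or
    'none' (baseline-only).
    """

    neuron_id: int
    modality: str
    baseline_rate: float = 0.1  # events/s
    gain: float = 2.0  # added events/s at full drive
    field_center_cm: float | None = None
    field_width_cm: float | None = None
    state_gains: dict | None = None
    response_latency_s: float | None = None
    response_duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("place", "visual", "auditory", "none"):
            raise InvalidParameterError(f"unknown tuning modality {self.modality!r}")
        if self.modality == "none":
            if any(
                v is not None
                for v in (
                    self.field_center_cm,
                    self.field_width_cm,
                    self.state_gains,
                    self.response_latency_s,
                    self.response_duration_s,
                )
            ):
                raise InvalidParameterError("modality 'none' admits no tuning parameters")
        if self.modality == "place":
            if self.field_center_cm is None or self.field_width_cm is None:
                raise InvalidParameterError("place tuning needs field center and width")
            if self.field_width_cm <= 0:
                raise InvalidParameterError("field_width_cm must be > 0")
        if self.modality == "visual" and not self.state_gains:
            raise InvalidParameterError("visual tuning needs state_gains")
        if self.modality == "auditory":
            if not self.state_gains:
                raise InvalidParameterError("auditory tuning needs state_gains")
            if self.response_duration_s is not None and self.response_duration_s <= 0:
                raise InvalidParameterError("response_duration_s must be > 0")
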