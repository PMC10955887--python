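"""Pipeline configuration.

Defaults mirror the recording and analysis constants of the experiments the
package models: 30 fps acquisition, a 1.6 m linear track split into 2 cm
bins, a 1000-shuffle sensitivity test at the 95th percentile, a 5-frame
LSTM window, 150-frame (5 s) auditory epochs, and a constant-velocity
Kalman filter with Q = 1e-4 and R = 1 at dt = 1/30 s.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import InvalidParameterError, FormatError

MODALITIES = ("position", "visual", "auditory")


@dataclasses.dataclass(frozen=True)
class KalmanSettings:
    dt: float = 1.0 / 30.0
    q: float = 1e-4
    r: float = 1.0
    u_mode: str = "zero"  # {"zero", "finite_difference"}

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError(f"kalman.dt must be > 0, got {self.dt}")
        if self.q <= 0:
            raise InvalidParameterError(f"kalman.q must be > 0, got {self.q}")
        if self.r <= 0:
            raise InvalidParameterError(f"kalman.r must be > 0, got {self.r}")
        if self.u_mode not in ("zero", "finite_difference"):
            raise InvalidParameterError(
                f"kalman.u_mode must be 'zero' or 'finite_difference', got {self.u_mode!r}"
            )


#: default hyperparameter grids; the neural-net grids follow the protocol of
#: grid-searching hidden sizes, learning rate and training epochs with 5-fold CV.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "gnb": {},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "mlp": {"hidden": [32, 64, 128], "lr": [1e-3, 1e-4], "epochs": [20, 50]},
    "lstm": {"hidden": [32, 64, 128], "lr": [1e-3, 1e-4], "epochs": [20, 50]},
    "cnn": {"filters": [32, 64], "lr": [1e-3, 1e-4], "epochs": [20, 50]},
}


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Validated bundle of every tunable constant in the pipeline."""

    fps: float = 30.0
    modality: str = "position"
    track_length_cm: float = 160.0
    bin_cm: float = 2.0
    n_shuffles: int = 1000
    percentile: float = 95.0
    lstm_window: int = 5
    epoch_frames: int = 150
    kalman: KalmanSettings = dataclasses.field(default_factory=KalmanSettings)
    grids: dict = dataclasses.field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GRIDS.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InvalidParameterError(f"fps must be > 0, got {self.fps}")
        if self.modality not in MODALITIES:
            raise InvalidParameterError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        if self.track_length_cm <= 0:
            raise InvalidParameterError(
                f"track_length_cm must be > 0, got {self.track_length_cm}"
            )
        if self.bin_cm <= 0:
            raise InvalidParameterError(f"bin_cm must be > 0, got {self.bin_cm}")
        if self.n_shuffles < 1:
            raise InvalidParameterError(f"n_shuffles must be >= 1, got {self.n_shuffles}")
        if not 0 < self.percentile < 100:
            raise InvalidParameterError(
                f"percentile must lie in (0, 100), got {self.percentile}"
            )
        if self.lstm_window < 1:
            raise InvalidParameterError(f"lstm_window must be >= 1, got {self.lstm_window}")
        if self.epoch_frames < 1:
            raise InvalidParameterError(f"epoch_frames must be >= 1, got {self.epoch_frames}")

    @property
    def frame_interval_ms(self) -> float:
        """Acquisition frame interval in milliseconds (1000 / fps)."""
        return 1000.0 / self.fps

    @property
    def n_bins(self) -> int:
        import math

        return math.ceil(self.track_length_cm / self.bin_cm)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


_TOP_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}
_KALMAN_KEYS = {f.name for f in dataclasses.fields(KalmanSettings)}


def config_from_dict(data: Mapping[str, Any] | None) -> PipelineConfig:
    """Build a config from a (possibly partial) mapping, rejecting unknown keys."""
    data = dict(data or {})
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    if "kalman" in data and data["kalman"] is not None:
        kdata = dict(data["kalman"])
        kunknown = set(kdata) - _KALMAN_KEYS
        if kunknown:
            raise InvalidParameterError(f"unknown kalman config keys: {sorted(kunknown)}")
        data["kalman"] = KalmanSettings(**kdata)
    return PipelineConfig(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON config file; missing keys take the defaults above."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return PipelineConfig()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse config file {path}: {exc}") from exc
    if data is None:
        return PipelineConfig()
    if not isinstance(data, Mapping):
        raise FormatError(f"config file {path} must contain a mapping at top level")
    return config_from_dict(data)
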