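"""File I/O conventions.

Traces and footprints travel as HDF5 (``/traces`` [N x T] with an ``fps``
attribute, ``/neuron_ids``, ``/centroids`` [N x 2]); behavior tracks and
stimulus schedules as headered UTF-8 CSV; movies as multi-page unsigned
16-bit TIFF; reports as JSON.  ``write`` followed by ``read`` is the
identity for float64 traces and exact for integer frames and labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import BehaviorTrack, FrameStack, NeuronFootprint, StimulusSchedule, TraceMatrix
from .errors import FormatError

__all__ = [
    "write_traces",
    "read_traces",
    "write_behavior",
    "read_behavior",
    "write_schedule",
    "read_schedule",
    "write_movie",
    "read_movie",
    "write_footprints",
    "read_footprints",
    "write_report",
]


def write_traces(path: str | Path, traces: TraceMatrix) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("traces", data=traces.values)
        d.attrs["fps"] = traces.fps
        ids = np.asarray(traces.neuron_ids)
        if ids.dtype.kind in "OU":
            ids = ids.astype("S")
        f.create_dataset("neuron_ids", data=ids)


def read_traces(path: str | Path) -> TraceMatrix:
    with h5py.File(path, "r") as f:
        if "traces" not in f:
            raise FormatError(f"{path}: missing dataset /traces")
        values = f["traces"][...]
        fps = float(f["traces"].attrs.get("fps", 30.0))
        if "neuron_ids" in f:
            ids = f["neuron_ids"][...]
            if ids.dtype.kind == "S":
                ids = ids.astype(str)
        else:
            ids = np.arange(values.shape[0])
    return TraceMatrix(values, ids, fps)


def write_behavior(path: str | Path, track: BehaviorTrack) -> None:
    pd.DataFrame(
        {
            "frame": track.frame_index,
            "time_s": track.time_s,
            "position_cm": track.position_cm,
        }
    ).to_csv(path, index=False)


def read_behavior(
    path: str | Path, fps: float = 30.0, track_length_cm: float = 160.0
) -> BehaviorTrack:
    df = pd.read_csv(path)
    for col in ("frame", "position_cm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "time_s" in df.columns and len(df) > 1:
        dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
        if dt > 0:
            fps = 1.0 / dt
    return BehaviorTrack(
        df["frame"].to_numpy(), df["position_cm"].to_numpy(), fps, track_length_cm
    )


def write_schedule(path: str | Path, schedule: StimulusSchedule) -> None:
    pd.DataFrame(
        {
            "frame": schedule.frame_index,
            "time_s": schedule.frame_index / schedule.fps,
            "state": schedule.state,
        }
    ).to_csv(path, index=False)


def read_schedule(path: str | Path, modality: str, fps: float = 30.0) -> StimulusSchedule:
    df = pd.read_csv(path)
    for col in ("frame", "state"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return StimulusSchedule(
        df["frame"].to_numpy(), df["state"].to_numpy(dtype=object), fps, modality
    )


def write_movie(path: str | Path, stack: FrameStack) -> None:
    frames = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack", metadata={"fps": stack.fps})


def read_movie(path: str | Path, fps: float = 30.0) -> FrameStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames, fps)


def write_footprints(path: str | Path, footprints: list[NeuronFootprint]) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "centroids",
            data=np.asarray([[fp.centroid_row, fp.centroid_col] for fp in footprints],
                            dtype=np.int64).reshape(-1, 2),
        )
        f.create_dataset("neuron_ids", data=np.asarray([fp.neuron_id for fp in footprints],
                                                        dtype=np.int64))


def read_footprints(path: str | Path) -> list[NeuronFootprint]:
    with h5py.File(path, "r") as f:
        if "centroids" not in f:
            raise FormatError(f"{path}: missing dataset /centroids")
        centroids = f["centroids"][...]
        ids = (
            f["neuron_ids"][...]
            if "neuron_ids" in f
            else np.arange(centroids.shape[0])
        )
    return [
        NeuronFootprint(int(i), int(r), int(c))
        for i, (r, c) in zip(ids, centroids)
    ]


def write_rate_map(path: str | Path, rate_map) -> None:
    """Tuning map as HDF5: /raw, /zscore, /order (+ kind attribute)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("raw", data=rate_map.raw)
        f.create_dataset("zscore", data=rate_map.zscore)
        f.create_dataset("order", data=rate_map.order)
        f.attrs["kind"] = rate_map.kind


def read_rate_map(path: str | Path):
    from .tuning import RateMap

    with h5py.File(path, "r") as f:
        if "zscore" not in f:
            raise FormatError(f"{path}: missing dataset /zscore")
        return RateMap(
            f["raw"][...], f["zscore"][...], f["order"][...], str(f.attrs.get("kind", "spatial"))
        )


def write_stream_result(path_prefix: str | Path, result, report=None) -> None:
    """Write a real-time session: per-frame CSV plus a JSON summary.

    ``path_prefix`` gets ``.csv`` and ``.json`` suffixes appended.
    """
    prefix = Path(path_prefix)
    data = {"frame": result.frame_index, "predicted": result.predicted}
    if result.raw_position_cm is not None:
        data["raw_position_cm"] = result.raw_position_cm
        data["filtered_position_cm"] = result.filtered_position_cm
    for stage, values in result.latency_ms.items():
        if np.any(values > 0):
            data[f"latency_{stage}_ms"] = values[result.frame_index] if values.size != result.frame_index.size else values
    pd.DataFrame(data).to_csv(prefix.with_suffix(".csv"), index=False)
    summary = {
        "modality": result.modality,
        "granularity": result.granularity,
        "n_predictions": int(result.predicted.size),
        "warmup_frames": int(result.warmup_frames),
        "frames_over_budget": int(result.over_budget.sum()),
    }
    if report is not None:
        summary.update(
            mean_error=report.mean_error,
            median_error=report.median_error,
            error_rate_pct=report.error_rate_pct,
        )
    write_report(prefix.with_suffix(".json"), summary)


def write_report(path: str | Path, report: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default))
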