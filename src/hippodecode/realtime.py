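"""Training-session and real-time-session orchestration.

A *training session* runs offline: (optional) registration and trace
extraction from a movie, shuffle-test neuron selection, chronological
75/25 split, training of the requested decoder families on the first 75%
of frames, holdout evaluation on the remaining 25%, selection of the best
model, and (for position) attachment of the Kalman post-filter.

A *real-time session* replays a stream frame by frame through the frozen
artifacts: register -> extract sensitive traces -> normalize -> decode,
with the position output additionally Kalman-filtered and per-stage
wall-clock latency recorded against the 33 ms frame budget (the budget is
logged, never enforced by dropping frames).
"""

from __future__ import annotations

import dataclasses
import time
from typing import Iterable, Sequence

import numpy as np

from .config import KalmanSettings, PipelineConfig
from .core import BehaviorTrack, FrameStack, NeuronFootprint, StimulusSchedule, TraceMatrix
from .decoders import DecoderModel, make_epochs, make_windows, predict, train_decoder
from .errors import InsufficientDataError, InvalidParameterError, ShapeError
from .imaging import extract_traces, register_frame
from .kalman import KalmanConfig, kalman_filter
from .tuning import (
    OccupancyBinning,
    RateMap,
    TuningResult,
    bin_occupancy,
    event_triggered_map,
    place_field_map,
    population_shuffle_test,
)

__all__ = [
    "SessionArtifacts",
    "StreamResult",
    "ErrorReport",
    "run_training_session",
    "run_realtime_session",
    "decode_offline",
    "evaluate_decoding",
    "top_sensitive_ids",
]

FRAME_BUDGET_MS = 1000.0 / 30.0  # 33.3 ms at 30 fps

#: decoder families evaluated per modality when none are requested explicitly
DEFAULT_KINDS = {
    "position": ("gnb", "svm", "mlp", "lstm"),
    "visual": ("gnb", "svm", "mlp"),
    "auditory": ("cnn",),
}
#: simplicity order used to break holdout-performance ties
SIMPLICITY = {"gnb": 0, "svm": 1, "mlp": 2, "lstm": 3, "cnn": 4}


@dataclasses.dataclass
class SessionArtifacts:
    """Everything a real-time session needs, frozen at training time."""

    modality: str
    config: PipelineConfig
    sensitive_ids: np.ndarray
    tuning_results: list[TuningResult]
    binning: OccupancyBinning
    models: dict[str, DecoderModel]
    holdout_errors: dict[str, float]
    best_kind: str
    kalman: KalmanSettings | None
    maps: RateMap
    fps: float
    seed: int

    @property
    def model(self) -> DecoderModel:
        return self.models[self.best_kind]

    def bin_center_cm(self, bin_index) -> np.ndarray:
        """Center (cm) of a spatial bin index (position modality only)."""
        return (np.asarray(bin_index, dtype=np.float64) + 0.5) * self.config.bin_cm


@dataclasses.dataclass
class StreamResult:
    """Per-frame (or per-epoch) decoding record of a real-time session."""

    modality: str
    granularity: str  # "frame" or "epoch"
    frame_index: np.ndarray
    predicted: np.ndarray
    raw_position_cm: np.ndarray | None
    filtered_position_cm: np.ndarray | None
    latency_ms: dict[str, np.ndarray]
    over_budget: np.ndarray
    warmup_frames: int


@dataclasses.dataclass
class ErrorReport:
    """Decoding-error summary.

    Position: per-frame |decoded bin center - true position| in cm with
    mean/median and a cumulative-fraction curve on a 1 cm grid.
    Classification: per-sample error rate (%) and a confusion table.
    """

    modality: str
    per_sample_error: np.ndarray
    mean_error: float
    median_error: float
    error_rate_pct: float | None
    cumulative_grid_cm: np.ndarray | None
    cumulative_fraction: np.ndarray | None
    confusion: np.ndarray | None
    confusion_labels: np.ndarray | None


def top_sensitive_ids(results: Sequence[TuningResult], fraction: float = 1.0) -> np.ndarray:
    """Ids of sensitive neurons, strongest first, truncated to ``fraction``."""
    if not 0 < fraction <= 1:
        raise InvalidParameterError(f"fraction must be in (0, 1], got {fraction}")
    sens = [r for r in results if r.sensitive]
    sens.sort(key=lambda r: -r.i_obs)
    k = max(1, int(round(fraction * len(sens)))) if sens else 0
    return np.asarray([r.neuron_id for r in sens[:k]])


def _frame_labels(modality: str, binning: OccupancyBinning, driver) -> np.ndarray:
    if modality == "position":
        return binning.frame_to_bin.copy()
    return np.asarray(driver.state, dtype=object)


def _position_error_cm(pred_bins, truth_pos, bin_cm: float) -> np.ndarray:
    centers = (np.asarray(pred_bins, dtype=np.float64) + 0.5) * bin_cm
    return np.abs(centers - np.asarray(truth_pos, dtype=np.float64))


def _holdout_error(modality, model, x_test, y_test, truth_pos, bin_cm) -> float:
    labels, _ = predict(model, x_test)
    if modality == "position":
        return float(np.mean(_position_error_cm(labels, truth_pos, bin_cm)))
    return float(100.0 * np.mean(labels != y_test))


def run_training_session(
    data: TraceMatrix | FrameStack,
    driver: BehaviorTrack | StimulusSchedule,
    config: PipelineConfig | None = None,
    decoder_kinds: Sequence[str] | None = None,
    footprints: Sequence[NeuronFootprint] | None = None,
    grids: dict | None = None,
) -> SessionArtifacts:
    """Build frozen decoding artifacts from a training recording."""
    config = config or PipelineConfig()
    modality = config.modality
    if isinstance(data, FrameStack):
        if footprints is None:
            raise InvalidParameterError("footprints are required when training from a movie")
        from .imaging import register_stack

        registered, _ = register_stack(data)
        traces = extract_traces(registered, footprints)
    else:
        traces = data

    if driver.n_frames != traces.n_frames:
        raise ShapeError(
            f"driver covers {driver.n_frames} frames but traces have {traces.n_frames}"
        )

    if modality == "position":
        if not isinstance(driver, BehaviorTrack):
            raise InvalidParameterError("position modality requires a behavior track")
        binning = bin_occupancy(driver, config.bin_cm)
    else:
        if not isinstance(driver, StimulusSchedule):
            raise InvalidParameterError(f"{modality} modality requires a stimulus schedule")
        binning = bin_occupancy(driver)

    results = population_shuffle_test(
        traces,
        binning,
        n_shuffles=config.n_shuffles,
        percentile=config.percentile,
        seed=config.seed,
    )
    sensitive_ids = np.asarray([r.neuron_id for r in results if r.sensitive])
    if sensitive_ids.size == 0:
        raise InsufficientDataError(
            "no sensitive neurons survived the shuffle test; cannot train a decoder"
        )
    sens_traces = traces.subset(sensitive_ids)

    labels = _frame_labels(modality, binning, driver)
    t = sens_traces.n_frames
    split = int(round(0.75 * t))

    kinds = tuple(decoder_kinds or DEFAULT_KINDS[modality])
    models: dict[str, DecoderModel] = {}
    holdout: dict[str, float] = {}
    x_frames = sens_traces.values.T  # frames x neurons
    for kind in kinds:
        grid = (grids or {}).get(kind)
        if kind == "lstm":
            w = config.lstm_window
            xw_tr, yw_tr = make_windows(sens_traces.values[:, :split], w, labels[:split])
            xw_te, yw_te = make_windows(sens_traces.values[:, split:], w, labels[split:])
            model = train_decoder(kind, xw_tr, yw_tr, grid=grid, seed=config.seed)
            if modality == "position":
                truth = driver.position_cm[split + w - 1 :]
                err = _holdout_error(modality, model, xw_te, yw_te, truth, config.bin_cm)
            else:
                err = _holdout_error(modality, model, xw_te, yw_te, None, None)
        elif kind == "cnn":
            epochs = make_epochs(sens_traces, driver, e=config.epoch_frames)
            n_ep = epochs.n_epochs
            ep_split = int(round(0.75 * n_ep))
            xt = epochs.as_time_major()
            model = train_decoder(
                kind, xt[:ep_split], epochs.labels[:ep_split], grid=grid, seed=config.seed
            )
            err = _holdout_error(
                modality, model, xt[ep_split:], epochs.labels[ep_split:], None, None
            )
        else:
            model = train_decoder(kind, x_frames[:split], labels[:split], grid=grid, seed=config.seed)
            if modality == "position":
                err = _holdout_error(
                    modality,
                    model,
                    x_frames[split:],
                    labels[split:],
                    driver.position_cm[split:],
                    config.bin_cm,
                )
            else:
                err = _holdout_error(modality, model, x_frames[split:], labels[split:], None, None)
        models[kind] = model
        holdout[kind] = err

    best_kind = min(kinds, key=lambda k: (holdout[k], SIMPLICITY[k]))

    # the 75/25 split exists to *report* holdout performance; the deployed
    # model is refit on the whole training session with the selected
    # hyperparameters before the real-time session starts
    for kind in kinds:
        grid_one = {k: [v] for k, v in models[kind].best_params.items()}
        if kind == "lstm":
            xw, yw = make_windows(sens_traces, config.lstm_window, labels)
            models[kind] = train_decoder(kind, xw, yw, grid=grid_one, seed=config.seed)
        elif kind == "cnn":
            epochs = make_epochs(sens_traces, driver, e=config.epoch_frames)
            models[kind] = train_decoder(
                kind, epochs.as_time_major(), epochs.labels, grid=grid_one, seed=config.seed
            )
        else:
            models[kind] = train_decoder(kind, x_frames, labels, grid=grid_one, seed=config.seed)

    if modality == "position":
        maps = place_field_map(sens_traces, binning)
    else:
        window = (2.0, 2.0) if modality == "visual" else (0.0, config.epoch_frames / traces.fps)
        maps = event_triggered_map(sens_traces, driver, window=window)

    return SessionArtifacts(
        modality=modality,
        config=config,
        sensitive_ids=sensitive_ids,
        tuning_results=results,
        binning=binning,
        models=models,
        holdout_errors=holdout,
        best_kind=best_kind,
        kalman=config.kalman if modality == "position" else None,
        maps=maps,
        fps=traces.fps,
        seed=config.seed,
    )


def _stream_frames(data: TraceMatrix | FrameStack) -> Iterable[np.ndarray]:
    if isinstance(data, TraceMatrix):
        for t in range(data.n_frames):
            yield data.values[:, t]
    else:
        for t in range(data.n_frames):
            yield data.frames[t]


def run_realtime_session(
    stream: TraceMatrix | FrameStack,
    artifacts: SessionArtifacts,
    schedule: StimulusSchedule | None = None,
    footprints: Sequence[NeuronFootprint] | None = None,
    template: np.ndarray | None = None,
) -> StreamResult:
    """Decode a stream frame by frame with the frozen training artifacts.

    ``stream`` is either a trace matrix (columns are frames; rows must
    cover the sensitive neuron set) or a movie (then ``footprints`` and a
    registration ``template`` are required).  Auditory sessions buffer one
    150-frame epoch per known tone onset from ``schedule`` and emit one
    prediction per epoch.  LSTM models keep a W-frame ring buffer and emit
    no prediction during the first W-1 warm-up frames.
    """
    model = artifacts.model
    from_movie = isinstance(stream, FrameStack)
    if from_movie and footprints is None:
        raise InvalidParameterError("footprints are required to stream a movie")
    if not from_movie:
        stream = stream.subset(artifacts.sensitive_ids)  # raises on mismatch
        fp_order = None
    else:
        by_id = {fp.neuron_id: fp for fp in footprints}
        missing = [i for i in artifacts.sensitive_ids.tolist() if i not in by_id]
        if missing:
            raise InvalidParameterError(f"stream lacks footprints for sensitive neurons {missing}")
        fp_order = [by_id[i] for i in artifacts.sensitive_ids.tolist()]
        if template is None:
            template = stream.frames[0].astype(np.float64)

    onset_set = set()
    if artifacts.modality == "auditory":
        if schedule is None:
            raise InvalidParameterError("auditory streaming requires the stimulus schedule")
        onset_set = set(schedule.epoch_onsets().tolist())

    e_frames = artifacts.config.epoch_frames
    w = model.window or 1
    is_window = model.contract == "window"
    is_epoch = model.contract == "epoch"

    records_frame: list[int] = []
    records_pred: list = []
    stage_names = ("register", "extract", "normalize", "decode", "filter")
    latencies: dict[str, list[float]] = {s: [] for s in stage_names}
    over_budget: list[bool] = []
    ring: list[np.ndarray] = []
    epoch_buffers: list[tuple[int, list[np.ndarray]]] = []
    warmup = 0

    from .kalman import KalmanConfig, KalmanState, kalman_step

    kstate = KalmanState.initial()
    kconf = (
        KalmanConfig.from_settings(artifacts.kalman)
        if artifacts.kalman is not None
        else None
    )
    filtered: list[float] = []
    raw_pos: list[float] = []

    n_frames = stream.n_frames
    for t in range(n_frames):
        lat = dict.fromkeys(stage_names, 0.0)
        t0 = time.perf_counter()
        if from_movie:
            (_, registered) = register_frame(stream.frames[t].astype(np.float64), template)
            t1 = time.perf_counter()
            lat["register"] = (t1 - t0) * 1e3
            patchvals = np.array(
                [
                    registered[fp.centroid_row - 1 : fp.centroid_row + 2,
                               fp.centroid_col - 1 : fp.centroid_col + 2].mean()
                    for fp in fp_order
                ]
            )
            frame_vec = patchvals
            lat["extract"] = (time.perf_counter() - t1) * 1e3
        else:
            frame_vec = stream.values[:, t]

        pred = None
        if is_epoch:
            if t in onset_set:
                epoch_buffers.append((t, []))
            done = []
            for onset, buf in epoch_buffers:
                buf.append(frame_vec)
                if len(buf) == e_frames:
                    done.append((onset, buf))
            if done:
                td = time.perf_counter()
                done_onsets = set()
                for onset, buf in done:
                    x = np.stack(buf)  # E x neurons (time-major)
                    label, _ = predict(model, x)
                    records_frame.append(onset)
                    records_pred.append(label)
                    done_onsets.add(onset)
                lat["decode"] = (time.perf_counter() - td) * 1e3
                epoch_buffers = [eb for eb in epoch_buffers if eb[0] not in done_onsets]
        elif is_window:
            ring.append(frame_vec)
            if len(ring) > w:
                ring.pop(0)
            if len(ring) == w:
                td = time.perf_counter()
                pred, _ = predict(model, np.stack(ring))
                lat["decode"] = (time.perf_counter() - td) * 1e3
            else:
                warmup += 1
        else:
            td = time.perf_counter()
            pred, _ = predict(model, frame_vec)
            lat["decode"] = (time.perf_counter() - td) * 1e3

        if pred is not None:
            records_frame.append(t)
            records_pred.append(pred)
            if artifacts.modality == "position":
                tf = time.perf_counter()
                z = float(artifacts.bin_center_cm(pred))
                kstate = kalman_step(kstate, z, kconf)
                raw_pos.append(z)
                filtered.append(
                    float(np.clip(kstate.x[0], 0.0, artifacts.config.track_length_cm))
                )
                lat["filter"] = (time.perf_counter() - tf) * 1e3

        for s in stage_names:
            latencies[s].append(lat[s])
        over_budget.append(sum(lat.values()) > FRAME_BUDGET_MS)

    return StreamResult(
        modality=artifacts.modality,
        granularity="epoch" if is_epoch else "frame",
        frame_index=np.asarray(records_frame, dtype=np.int64),
        predicted=np.asarray(records_pred, dtype=object)
        if artifacts.modality != "position"
        else np.asarray(records_pred, dtype=np.int64),
        raw_position_cm=np.asarray(raw_pos) if raw_pos else None,
        filtered_position_cm=np.asarray(filtered) if filtered else None,
        latency_ms={s: np.asarray(v) for s, v in latencies.items()},
        over_budget=np.asarray(over_budget, dtype=bool),
        warmup_frames=warmup,
    )


def decode_offline(artifacts: SessionArtifacts, traces: TraceMatrix,
                   schedule: StimulusSchedule | None = None):
    """Batch decoding of a full recording with the frozen artifacts.

    Returns ``(frame_index, labels)`` aligned exactly as the streaming
    path would emit them (LSTM predictions start at frame W-1; auditory
    predictions are anchored at epoch onsets).
    """
    model = artifacts.model
    sens = traces.subset(artifacts.sensitive_ids)
    if model.contract == "frame":
        labels, _ = predict(model, sens.values.T)
        return np.arange(sens.n_frames), labels
    if model.contract == "window":
        w = model.window
        x, _ = make_windows(sens, w, np.zeros(sens.n_frames))
        labels, _ = predict(model, x)
        return np.arange(w - 1, sens.n_frames), labels
    if schedule is None:
        raise InvalidParameterError("epoch decoding requires the stimulus schedule")
    epochs = make_epochs(sens, schedule, e=artifacts.config.epoch_frames)
    onsets = schedule.epoch_onsets()
    keep = onsets + artifacts.config.epoch_frames <= sens.n_frames
    labels, _ = predict(model, epochs.as_time_major())
    return onsets[keep], labels


def evaluate_decoding(
    result: StreamResult,
    truth,
    bin_cm: float | None = None,
    use_filtered: bool = True,
) -> ErrorReport:
    """Score a stream against ground truth.

    ``truth`` is a behavior track or per-frame position array (position
    modality; indexed by the result's frame_index) or a per-sample label
    array aligned with the result's predictions (classification).
    """
    if result.modality == "position":
        if isinstance(truth, BehaviorTrack):
            truth_pos = truth.position_cm[result.frame_index]
        else:
            truth_arr = np.asarray(truth, dtype=np.float64)
            truth_pos = (
                truth_arr[result.frame_index]
                if truth_arr.size != result.frame_index.size
                else truth_arr
            )
        pred_pos = (
            result.filtered_position_cm
            if (use_filtered and result.filtered_position_cm is not None)
            else result.raw_position_cm
        )
        if pred_pos.size != truth_pos.size:
            raise ShapeError("truth and predictions have different lengths")
        err = np.abs(pred_pos - truth_pos)
        grid = np.arange(0.0, max(err.max(), 1.0) + 1.0, 1.0)
        cum = np.asarray([(err <= g).mean() for g in grid])
        return ErrorReport(
            modality="position",
            per_sample_error=err,
            mean_error=float(err.mean()),
            median_error=float(np.median(err)),
            error_rate_pct=None,
            cumulative_grid_cm=grid,
            cumulative_fraction=cum,
            confusion=None,
            confusion_labels=None,
        )

    truth_labels = np.asarray(truth, dtype=object)
    if truth_labels.size != result.predicted.size:
        raise ShapeError(
            f"{truth_labels.size} truth labels for {result.predicted.size} predictions"
        )
    wrong = (result.predicted != truth_labels).astype(np.float64)
    labels = np.unique(np.concatenate([truth_labels, result.predicted]))
    lut = {c: i for i, c in enumerate(labels.tolist())}
    confusion = np.zeros((labels.size, labels.size), dtype=np.int64)
    for tl, pl in zip(truth_labels, result.predicted):
        confusion[lut[tl], lut[pl]] += 1
    return ErrorReport(
        modality=result.modality,
        per_sample_error=wrong,
        mean_error=float(wrong.mean()),
        median_error=float(np.median(wrong)),
        error_rate_pct=float(100.0 * wrong.mean()),
        cumulative_grid_cm=None,
        cumulative_fraction=None,
        confusion=confusion,
        confusion_labels=labels,
    )
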