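"""Neuron selection and tuning diagnostics.

Spatial (or stimulus-state) occupancy binning, Skaggs-style information
content computed on raw fluorescence, a shuffle-based sensitivity test,
place-field and peri-stimulus maps, and the normalized cross-correlation
used to compare rate maps across sessions.

Information content for one neuron is the occupancy-weighted sum

    I = sum_i p_i (r_i / rbar) log2(r_i / rbar),   rbar = sum_i p_i r_i,

with p_i the occupancy probability of bin i and r_i the mean fluorescence
in bin i; terms with r_i = 0 contribute 0, and I = 0 when rbar = 0.  The
per-bin contributions are exposed for inspection.  A neuron is *sensitive*
when its observed I strictly exceeds the 95th percentile of the null
distribution obtained by recomputing I after shuffling the behavioral
driver relative to the trace (1000 shuffles by default).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Literal

import numpy as np

from .core import AUDITORY_OFF, AUDITORY_STATES, BehaviorTrack, StimulusSchedule, TraceMatrix
from .errors import EmptyResultError, InvalidParameterError, ShapeError

__all__ = [
    "OccupancyBinning",
    "TuningResult",
    "RateMap",
    "CrossCorrMap",
    "bin_occupancy",
    "information_content",
    "shuffle_test",
    "population_shuffle_test",
    "place_field_map",
    "event_triggered_map",
    "rate_map_crosscorr",
]


@dataclasses.dataclass
class OccupancyBinning:
    """Frame-to-bin map with occupancy probabilities.

    ``frame_to_bin`` holds one bin index per frame; -1 marks excluded
    frames (e.g. tone-off frames in strict auditory mode).  ``p`` sums to 1
    over the included frames.
    """

    kind: Literal["spatial", "state"]
    k: int
    labels: list  # bin centers (cm) for spatial, state names for state bins
    p: np.ndarray
    frame_to_bin: np.ndarray
    bin_cm: float | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        self.frame_to_bin = np.asarray(self.frame_to_bin, dtype=np.int64)
        if self.p.shape != (self.k,):
            raise ShapeError("p must have one entry per bin")
        if self.p.size and (self.p.min() < 0 or abs(self.p.sum() - 1.0) > 1e-9):
            raise InvalidParameterError("occupancy probabilities must be >= 0 and sum to 1")

    @property
    def n_frames(self) -> int:
        return self.frame_to_bin.size


def bin_occupancy(
    driver: BehaviorTrack | StimulusSchedule,
    bin_cm: float | None = None,
    auditory_frames: Literal["epoch", "tone_on"] = "epoch",
) -> OccupancyBinning:
    """Assign every frame to an occupancy bin.

    Spatial mode (``driver`` is a behavior track): ``k = ceil(L / bin_cm)``
    half-open bins ``[left, right)`` with the last bin closed.

    State mode (``driver`` is a stimulus schedule): one bin per stimulus
    state.  For auditory schedules the default assigns every frame of a 5 s
    epoch (tone + following silence) the epoch's frequency label;
    ``auditory_frames='tone_on'`` restricts to tone-on frames and excludes
    the rest.
    """
    if isinstance(driver, BehaviorTrack):
        if driver.n_frames == 0:
            raise InvalidParameterError("empty behavior track")
        if bin_cm is None or bin_cm <= 0:
            raise InvalidParameterError("spatial binning requires bin_cm > 0")
        k = math.ceil(driver.track_length_cm / bin_cm)
        idx = np.floor(driver.position_cm / bin_cm).astype(np.int64)
        idx[idx >= k] = k - 1  # close the last bin at position == track length
        counts = np.bincount(idx, minlength=k).astype(np.float64)
        p = counts / counts.sum()
        centers = [(i + 0.5) * bin_cm for i in range(k)]
        if np.count_nonzero(counts) <= 1:
            warnings.warn("all frames fall in a single spatial bin; information content will be 0")
        return OccupancyBinning("spatial", k, centers, p, idx, bin_cm=bin_cm)

    if not isinstance(driver, StimulusSchedule):
        raise InvalidParameterError(f"unsupported driver type {type(driver).__name__}")
    if driver.n_frames == 0:
        raise InvalidParameterError("empty stimulus schedule")
    if driver.modality == "visual":
        states = ["light", "dark"]
        idx = np.asarray([states.index(s) for s in driver.state], dtype=np.int64)
    else:
        states = list(AUDITORY_STATES)
        lut = {s: i for i, s in enumerate(states)}
        idx = np.empty(driver.n_frames, dtype=np.int64)
        current = -1
        for t, s in enumerate(driver.state):
            if s == AUDITORY_OFF:
                idx[t] = current if auditory_frames == "epoch" else -1
            else:
                current = lut[s]
                idx[t] = current
    included = idx >= 0
    counts = np.bincount(idx[included], minlength=len(states)).astype(np.float64)
    if counts.sum() == 0:
        raise InvalidParameterError("no frames assigned to any state bin")
    p = counts / counts.sum()
    if np.count_nonzero(counts) <= 1:
        warnings.warn("all frames fall in a single state bin; information content will be 0")
    return OccupancyBinning("state", len(states), states, p, idx)


def _prepare_trace(trace: np.ndarray) -> np.ndarray:
    trace = np.asarray(trace, dtype=np.float64)
    if trace.min() < 0:
        trace = trace - trace.min()  # raw intensity should be non-negative
    return trace


def _info_from_sums(sums: np.ndarray, counts: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Information content from per-bin trace sums.

    ``sums`` is ... x k (leading axes = neurons and/or shuffles); unvisited
    bins (count 0) contribute 0 to both the mean rate and the sum.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        rbar = (p * r).sum(axis=-1, keepdims=True)
        ratio = np.where(rbar > 0, r / np.where(rbar > 0, rbar, 1.0), 0.0)
        terms = np.where(ratio > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return terms.sum(axis=-1)


def information_content(
    trace: np.ndarray,
    binning: OccupancyBinning,
    return_contributions: bool = False,
):
    """Skaggs-style information content (bits) of one neuron's trace."""
    trace = _prepare_trace(trace)
    if trace.shape != (binning.n_frames,):
        raise ShapeError(
            f"trace length {trace.shape} does not match driver length ({binning.n_frames},)"
        )
    idx = binning.frame_to_bin
    inc = idx >= 0
    counts = np.bincount(idx[inc], minlength=binning.k).astype(np.float64)
    sums = np.bincount(idx[inc], weights=trace[inc], minlength=binning.k)
    info = float(_info_from_sums(sums[None, :], counts, binning.p)[0])
    if not return_contributions:
        return info
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        rbar = float((binning.p * r).sum())
        ratio = np.where(rbar > 0, r / rbar, 0.0)
        contributions = np.where(ratio > 0, binning.p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return info, contributions


@dataclasses.dataclass
class TuningResult:
    """Observed information content against its shuffle null for one neuron."""

    neuron_id: int
    i_obs: float
    null_i: np.ndarray
    percentile_rank: float  # % of null values strictly below i_obs
    sensitive: bool


def _shuffled_bins(
    idx: np.ndarray, method: str, rng: np.random.Generator, fps: int
) -> np.ndarray:
    t = idx.size
    if method == "circular":
        lo, hi = min(fps, t - 1), max(t - fps, fps + 1)
        offset = int(rng.integers(lo, hi)) if hi > lo else int(rng.integers(1, t))
        return np.roll(idx, offset)
    if method == "permute":
        return idx[rng.permutation(t)]
    if method == "blocks":
        # permute contiguous same-state runs; preserves within-block trace
        # autocorrelation while destroying stimulus alignment — the right
        # null for periodic stimulus schedules, where circular shifts can
        # re-align the driver with itself
        boundaries = np.flatnonzero(np.diff(idx)) + 1
        segments = np.split(idx, boundaries)
        order = rng.permutation(len(segments))
        return np.concatenate([segments[i] for i in order])
    raise InvalidParameterError(f"unknown shuffle method {method!r}")


def population_shuffle_test(
    traces: TraceMatrix,
    binning: OccupancyBinning,
    n_shuffles: int = 1000,
    percentile: float = 95.0,
    method: Literal["auto", "circular", "permute", "blocks"] = "auto",
    seed: int = 0,
) -> list[TuningResult]:
    """Shuffle sensitivity test for every neuron in a trace matrix.

    The null is built by recomputing information content after displacing
    the frame-to-bin map relative to the traces: ``circular`` rotates it by
    a random offset uniform in [fps, T - fps] frames (preserving trace
    autocorrelation), ``permute`` draws a full random permutation, and
    ``blocks`` permutes whole same-state blocks.  ``auto`` picks circular
    for spatial binning and blocks for stimulus-state binning.  A neuron
    is sensitive when its observed value strictly exceeds the
    ``percentile``-th percentile (linear-interpolation quantile) of its own
    null.  All neurons share the same shuffle draws.
    """
    if method == "auto":
        method = "circular" if binning.kind == "spatial" else "blocks"
    if n_shuffles < 1:
        raise InvalidParameterError(f"n_shuffles must be >= 1, got {n_shuffles}")
    if traces.n_frames != binning.n_frames:
        raise ShapeError(
            f"traces have {traces.n_frames} frames but the driver has {binning.n_frames}"
        )
    rng = np.random.default_rng(seed)
    x = traces.values
    if x.size and x.min() < 0:
        x = x - x.min(axis=1, keepdims=True).clip(max=0.0)

    idx_full = binning.frame_to_bin
    inc = idx_full >= 0
    idx = idx_full[inc]
    x = x[:, inc]
    n, t = x.shape
    k = binning.k
    counts = np.bincount(idx, minlength=k).astype(np.float64)

    onehot = np.zeros((t, k))
    onehot[np.arange(t), idx] = 1.0
    i_obs = _info_from_sums(x @ onehot, counts, binning.p)

    fps = int(round(traces.fps))
    null = np.empty((n_shuffles, n))
    if method == "circular":
        # rotating each trace is the same null as rotating the driver, but
        # lets every neuron draw an independent offset — with a shared
        # offset the per-neuron thresholds co-vary and the session-level
        # rejection rate becomes needlessly noisy
        lo, hi = min(fps, t - 1), max(t - fps, fps + 1)
        col_base = np.arange(t)[None, :]
        row_index = np.arange(n)[:, None]
        for s in range(n_shuffles):
            if hi > lo:
                offsets = rng.integers(lo, hi, size=n)
            else:
                offsets = rng.integers(1, t, size=n)
            x_s = x[row_index, (col_base - offsets[:, None]) % t]
            null[s] = _info_from_sums(x_s @ onehot, counts, binning.p)
    else:
        for s in range(n_shuffles):
            idx_s = _shuffled_bins(idx, method, rng, fps)
            onehot_s = np.zeros((t, k))
            onehot_s[np.arange(t), idx_s] = 1.0
            null[s] = _info_from_sums(x @ onehot_s, counts, binning.p)

    results = []
    thresholds = np.quantile(null, percentile / 100.0, axis=0)
    for i in range(n):
        rank = 100.0 * float(np.mean(null[:, i] < i_obs[i]))
        results.append(
            TuningResult(
                neuron_id=traces.neuron_ids[i].item() if hasattr(traces.neuron_ids[i], "item") else traces.neuron_ids[i],
                i_obs=float(i_obs[i]),
                null_i=null[:, i].copy(),
                percentile_rank=rank,
                sensitive=bool(i_obs[i] > thresholds[i]),
            )
        )
    return results


def shuffle_test(
    trace: np.ndarray,
    binning: OccupancyBinning,
    n_shuffles: int = 1000,
    percentile: float = 95.0,
    method: Literal["auto", "circular", "permute", "blocks"] = "auto",
    seed: int = 0,
    fps: float = 30.0,
    neuron_id: int = 0,
) -> TuningResult:
    """Shuffle sensitivity test for a single trace (see population_shuffle_test)."""
    tm = TraceMatrix(np.asarray(trace, dtype=np.float64)[None, :], np.asarray([neuron_id]), fps)
    return population_shuffle_test(tm, binning, n_shuffles, percentile, method, seed)[0]


@dataclasses.dataclass
class RateMap:
    """Mean-fluorescence map (neurons x bins) and its per-row z-scored form."""

    raw: np.ndarray
    zscore: np.ndarray
    order: np.ndarray  # row order applied (identity if unsorted)
    kind: str  # "spatial" or "temporal"
    neuron_ids: np.ndarray | None = None


def _zscore_rows(raw: np.ndarray) -> np.ndarray:
    mean = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)
    degenerate = (sd == 0).ravel()
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance rows z-scored to 0")
    z = np.where(sd > 0, (raw - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def place_field_map(
    traces: TraceMatrix, binning: OccupancyBinning, sort: bool = True
) -> RateMap:
    """Mean fluorescence of each neuron per spatial bin, z-scored per neuron.

    With ``sort`` the rows are ordered by the location of their peak
    (ties broken toward the lower bin), which renders a population of place
    cells as a diagonal ridge.
    """
    if binning.kind != "spatial":
        raise InvalidParameterError("place_field_map requires spatial binning")
    if traces.n_frames != binning.n_frames:
        raise ShapeError("traces and binning cover different numbers of frames")
    idx = binning.frame_to_bin
    counts = np.bincount(idx, minlength=binning.k).astype(np.float64)
    onehot = np.zeros((idx.size, binning.k))
    onehot[np.arange(idx.size), idx] = 1.0
    raw = (traces.values @ onehot) / np.maximum(counts, 1.0)
    z = _zscore_rows(raw)
    order = np.arange(raw.shape[0])
    if sort:
        order = np.argsort(np.argmax(z, axis=1), kind="stable")
        raw, z = raw[order], z[order]
    return RateMap(raw, z, order, "spatial", neuron_ids=traces.neuron_ids[order])


def event_triggered_map(
    traces: TraceMatrix,
    schedule: StimulusSchedule,
    window: tuple[float, float] = (0.0, 5.0),
) -> RateMap:
    """Average trace segments aligned to stimulus onsets, z-scored per neuron.

    ``window = (pre_s, post_s)`` spans ``[-pre_s, +post_s)`` around each
    onset; windows extending beyond the recording are dropped.
    """
    pre_s, post_s = window
    fps = traces.fps
    pre_f = int(round(pre_s * fps))
    post_f = int(round(post_s * fps))
    if pre_f + post_f < 1:
        raise InvalidParameterError("window must span at least one frame")
    onsets = schedule.epoch_onsets()
    if onsets.size == 0:
        raise EmptyResultError("schedule contains no stimulus onsets")
    segments = []
    for onset in onsets:
        a, b = onset - pre_f, onset + post_f
        if a < 0 or b > traces.n_frames:
            continue
        segments.append(traces.values[:, a:b])
    if not segments:
        raise EmptyResultError("no stimulus window fits inside the recording")
    raw = np.mean(segments, axis=0)
    z = _zscore_rows(raw)
    return RateMap(raw, z, np.arange(raw.shape[0]), "temporal", neuron_ids=traces.neuron_ids)


@dataclasses.dataclass
class CrossCorrMap:
    """Normalized cross-correlation over integer shifts of one map on another."""

    shifts_u: np.ndarray
    shifts_v: np.ndarray
    r: np.ndarray  # len(shifts_u) x len(shifts_v); NaN where undefined
    peak_value: float
    peak_shift: tuple[int, int]


def rate_map_crosscorr(
    m: np.ndarray, n: np.ndarray, max_shift: tuple[int, int] | None = None
) -> CrossCorrMap:
    """Normalized cross-correlation between two rate maps.

    At each integer shift (u, v) the second map is displaced and the
    correlation is computed over the overlap, centering the first map by
    its overlap-local mean and the second by its global mean:

        R(u,v) = sum[(m - mbar_{u,v}) (n_shifted - nbar)]
                 / sqrt(sum (m - mbar_{u,v})^2 * sum (n_shifted - nbar)^2)

    Shifts whose overlap has fewer than 4 elements or zero variance in
    either map are undefined (NaN) and excluded from the peak search.
    """
    m = np.atleast_2d(np.asarray(m, dtype=np.float64))
    n = np.atleast_2d(np.asarray(n, dtype=np.float64))
    if m.shape != n.shape:
        raise ShapeError(f"maps must have identical shape, got {m.shape} vs {n.shape}")
    if np.ptp(m) == 0 or np.ptp(n) == 0:
        raise InvalidParameterError("fully constant map; cross-correlation is undefined")
    h, w = m.shape
    mu = max_shift[0] if max_shift else h - 1
    mv = max_shift[1] if max_shift else w - 1
    shifts_u = np.arange(-mu, mu + 1)
    shifts_v = np.arange(-mv, mv + 1)
    nbar = n.mean()
    r = np.full((shifts_u.size, shifts_v.size), np.nan)
    for iu, u in enumerate(shifts_u):
        for iv, v in enumerate(shifts_v):
            # overlap in m coordinates: (x, y) with (x-u, y-v) inside n
            x0, x1 = max(0, u), min(h, h + u)
            y0, y1 = max(0, v), min(w, w + v)
            if (x1 - x0) * (y1 - y0) < 4:
                continue
            mm = m[x0:x1, y0:y1]
            nn = n[x0 - u : x1 - u, y0 - v : y1 - v]
            mc = mm - mm.mean()
            nc = nn - nbar
            den = math.sqrt((mc**2).sum() * (nc**2).sum())
            if den == 0:
                continue
            r[iu, iv] = float((mc * nc).sum() / den)
    if np.all(np.isnan(r)):
        raise InvalidParameterError("cross-correlation undefined at every shift")
    flat = np.nanargmax(r)
    pu, pv = np.unravel_index(flat, r.shape)
    return CrossCorrMap(
        shifts_u,
        shifts_v,
        r,
        float(r[pu, pv]),
        (int(shifts_u[pu]), int(shifts_v[pv])),
    )
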