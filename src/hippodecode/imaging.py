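"""Frame registration, trace extraction, and the noise-level statistic.

Registration is translational only, by upsampled frequency-domain
cross-correlation.  Raw calcium activity of a neuron is the mean intensity
of the centroid pixel and its eight neighbours (a 3 x 3 patch).  The noise
level of a trace is the standard deviation of the residual left after
zero-phase lowpass filtering at 1 Hz.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.ndimage
import scipy.signal
from skimage.registration import phase_cross_correlation

from .core import FrameStack, NeuronFootprint, TraceMatrix
from .errors import DegenerateInputError, InvalidParameterError, ShapeError

__all__ = [
    "register_frame",
    "register_stack",
    "extract_traces",
    "noise_level",
    "NoiseProfile",
]


def register_frame(
    frame: np.ndarray,
    template: np.ndarray,
    upsample: int = 1,
) -> tuple[tuple[float, float], np.ndarray]:
    """Estimate the rigid shift of ``frame`` relative to ``template``.

    Returns ``(shift, registered)`` where ``shift = (dy, dx)`` is the
    translation that produced ``frame`` from ``template`` (i.e.
    ``frame ≈ translate(template, shift)``) and ``registered`` is ``frame``
    translated by ``-shift`` back onto the template, with revealed edges
    filled with the frame median.  ``upsample > 1`` enables subpixel
    estimation via upsampled frequency-domain correlation.
    """
    frame = np.asarray(frame, dtype=np.float64)
    template = np.asarray(template, dtype=np.float64)
    if frame.shape != template.shape:
        raise ShapeError(f"frame {frame.shape} and template {template.shape} differ")
    if np.ptp(template) == 0:
        raise DegenerateInputError("template is constant; registration is undefined")
    if upsample < 1:
        raise InvalidParameterError(f"upsample must be >= 1, got {upsample}")

    # phase_cross_correlation returns the shift that maps `moving` onto
    # `reference`; with reference=template that is -shift in our convention.
    result = phase_cross_correlation(template, frame, upsample_factor=upsample)
    shift = tuple(-s for s in np.asarray(result[0], dtype=np.float64))
    fill = float(np.median(frame))
    order = 0 if upsample == 1 else 1
    registered = scipy.ndimage.shift(
        frame, [-shift[0], -shift[1]], order=order, mode="constant", cval=fill
    )
    return (float(shift[0]), float(shift[1])), registered


def register_stack(stack: FrameStack, template: np.ndarray | None = None, upsample: int = 1):
    """Register every frame of a stack against ``template`` (default: frame 0).

    Returns ``(registered_stack, shifts)`` with shifts as a T x 2 array.
    """
    frames = stack.frames.astype(np.float64)
    if template is None:
        if stack.n_frames == 0:
            raise InvalidParameterError("empty stack and no template")
        template = frames[0]
    shifts = np.zeros((stack.n_frames, 2))
    out = np.empty_like(frames)
    for t in range(stack.n_frames):
        (dy, dx), reg = register_frame(frames[t], template, upsample=upsample)
        shifts[t] = (dy, dx)
        out[t] = reg
    return FrameStack(out, stack.fps), shifts


def extract_traces(stack: FrameStack, footprints: Sequence[NeuronFootprint]) -> TraceMatrix:
    """Raw calcium activity: mean of the 3 x 3 patch around each centroid."""
    h, w = stack.frame_shape
    for fp in footprints:
        fp.validate_for((h, w))
    n = len(footprints)
    values = np.empty((n, stack.n_frames))
    frames = stack.frames
    for i, fp in enumerate(footprints):
        r, c = fp.centroid_row, fp.centroid_col
        patch = frames[:, r - 1 : r + 2, c - 1 : c + 2]
        values[i] = patch.mean(axis=(1, 2))
    ids = np.asarray([fp.neuron_id for fp in footprints])
    if n == 0:
        values = np.empty((0, stack.n_frames))
        ids = np.empty((0,), dtype=np.int64)
    return TraceMatrix(values, ids, stack.fps)


@dataclasses.dataclass
class NoiseProfile:
    """Residual traces (raw - lowpass) and their per-neuron sd."""

    residual: np.ndarray  # N x T
    noise_level: np.ndarray  # N
    cutoff_hz: float
    order: int


def noise_level(
    traces: TraceMatrix, cutoff_hz: float = 1.0, order: int = 20
) -> NoiseProfile:
    """Noise statistic: sd of (raw - zero-phase lowpassed raw) per neuron.

    The filter is a Butterworth lowpass of the stated order, factored into
    second-order sections and applied forward-backward, which doubles the
    effective attenuation while making the response zero-phase.
    """
    if traces.fps <= 2 * cutoff_hz:
        raise InvalidParameterError(
            f"fps={traces.fps} too low for a {cutoff_hz} Hz cutoff"
        )
    min_len = 6 * order
    if traces.n_frames <= min_len:
        raise InvalidParameterError(
            f"need more than {min_len} frames for stable order-{order} filtering, "
            f"got {traces.n_frames}"
        )
    sos = scipy.signal.butter(order, cutoff_hz, btype="low", fs=traces.fps, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, traces.values, axis=1)
    residual = traces.values - filtered
    return NoiseProfile(residual, residual.std(axis=1), cutoff_hz, order)
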