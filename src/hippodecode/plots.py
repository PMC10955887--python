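"""Diagnostic figures: trajectory overlay, error histogram, cumulative
fraction, and tuning-map heatmaps.  Each function draws onto a fresh (or
supplied) matplotlib Axes and returns it; saving is left to the caller."""

from __future__ import annotations

import numpy as np

from .realtime import ErrorReport, StreamResult
from .tuning import RateMap


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def trajectory_overlay(result: StreamResult, truth_cm: np.ndarray, fps: float = 30.0, ax=None):
    """True vs reconstructed position over time (the classic overlay plot)."""
    ax = _axes(ax)
    t = result.frame_index / fps
    ax.plot(t, truth_cm, color="tab:red", lw=1.0, label="tracked position")
    pred = (
        result.filtered_position_cm
        if result.filtered_position_cm is not None
        else result.raw_position_cm
    )
    ax.plot(t, pred, color="tab:blue", lw=1.0, label="reconstructed")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("position (cm)")
    ax.legend(frameon=False)
    return ax


def error_histogram(report: ErrorReport, bins: int = 40, ax=None):
    ax = _axes(ax)
    ax.hist(report.per_sample_error, bins=bins, color="tab:blue")
    unit = "cm" if report.modality == "position" else ""
    ax.set_xlabel(f"decoding error {unit}".strip())
    ax.set_ylabel("frames")
    return ax


def cumulative_fraction(report: ErrorReport, ax=None, **plot_kwargs):
    """Cumulative fraction of frames below each error level (position only)."""
    ax = _axes(ax)
    ax.plot(report.cumulative_grid_cm, report.cumulative_fraction, **plot_kwargs)
    ax.set_xlabel("decoding error (cm)")
    ax.set_ylabel("cumulative fraction")
    ax.set_ylim(0, 1.02)
    return ax


def tuning_heatmap(rate_map: RateMap, ax=None):
    """Z-scored tuning map (neurons x bins), e.g. a sorted place-field map."""
    ax = _axes(ax)
    im = ax.imshow(rate_map.zscore, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xlabel("spatial bin" if rate_map.kind == "spatial" else "frame in window")
    ax.set_ylabel("neuron (sorted)" if rate_map.kind == "spatial" else "neuron")
    ax.figure.colorbar(im, ax=ax, label="fluorescence z-score")
    return ax
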