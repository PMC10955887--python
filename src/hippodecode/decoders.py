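"""Decoder families and their shared framing/normalization utilities.

Five classifiers map population activity to a class label (a 2 cm position
bin, a light/dark state, or a tone frequency):

- ``gnb``  — Gaussian naive Bayes with occupancy priors, authored here:
  y_hat = argmax_y P(y) prod_i N(x_i | mu_y,i, sigma_y,i), evaluated in
  log space.
- ``svm``  — RBF-kernel support vector machine, gamma fixed to the
  reciprocal of the number of input features, C grid-searched.
- ``mlp``  — two ReLU hidden layers + softmax, Adam, batch size 32.
- ``lstm`` — two-layer LSTM over sliding windows (default 5 frames).
- ``cnn``  — temporal CNN over stimulus epochs (default 150 frames),
  consuming *raw* (unnormalized) intensities.

All except the CNN consume per-feature standardized inputs; the training
statistics are frozen into the model and re-applied verbatim to streaming
data.  Hyperparameters are chosen by mean five-fold cross-validated
accuracy over a grid, ties resolved toward the smaller model.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Literal, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .config import DEFAULT_GRIDS
from .core import StimulusSchedule, TraceMatrix
from .errors import (
    EmptyResultError,
    InsufficientDataError,
    InvalidParameterError,
    ShapeError,
)
from .nn import CNNClassifier, LSTMClassifier

__all__ = [
    "Normalizer",
    "GnbModel",
    "gnb_fit",
    "gnb_predict",
    "DecoderModel",
    "EpochTensor",
    "make_windows",
    "make_epochs",
    "train_decoder",
    "predict",
    "DECODER_KINDS",
]

DECODER_KINDS = ("gnb", "svm", "mlp", "lstm", "cnn")
SD_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# normalization

@dataclasses.dataclass
class Normalizer:
    """Per-feature standardization statistics estimated on training data."""

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.shape[-1] != self.mean.size:
            raise ShapeError(
                f"input has {x.shape[-1]} features, normalizer expects {self.mean.size}"
            )
        return (x - self.mean) / self.sd


def fit_normalizer(x_train: np.ndarray) -> Normalizer:
    """Fit mean/sd (population sd, floored at 1e-8) per feature column."""
    x_train = np.asarray(x_train, dtype=np.float64)
    if x_train.ndim != 2 or x_train.shape[0] < 2:
        raise InsufficientDataError("need a 2-D array with at least 2 training frames")
    mean = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    if np.any(sd < SD_FLOOR):
        warnings.warn(
            f"{int((sd < SD_FLOOR).sum())} zero-variance features; sd floored at {SD_FLOOR}"
        )
    return Normalizer(mean, np.maximum(sd, SD_FLOOR))


def apply_normalizer(normalizer: Normalizer, x: np.ndarray) -> np.ndarray:
    return normalizer.apply(x)


# ---------------------------------------------------------------------------
# Gaussian naive Bayes

@dataclasses.dataclass
class GnbModel:
    classes: np.ndarray
    priors: np.ndarray
    mu: np.ndarray  # classes x features
    sigma: np.ndarray  # classes x features (sd, floored)

    @property
    def n_features(self) -> int:
        return self.mu.shape[1]


def gnb_fit(x: np.ndarray, y: Sequence, uniform_priors: bool = False) -> GnbModel:
    """Fit the naive-Bayes decoder.

    Priors are the class frame fractions (the probability of occupancy of
    each bin in the training data) unless ``uniform_priors`` is set.  The
    per-class variance is floored at 1e-9 times the largest feature
    variance so constant features cannot produce degenerate likelihoods.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ShapeError("x must be frames x features aligned with y")
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < 2]
    if small.size:
        raise InsufficientDataError(f"classes {small.tolist()} have fewer than 2 frames")
    total_var = x.var(axis=0).max() if x.size else 0.0
    var_floor = max(1e-9 * total_var, 1e-12)
    mu = np.empty((classes.size, x.shape[1]))
    sigma = np.empty_like(mu)
    for i, c in enumerate(classes):
        xc = x[y == c]
        mu[i] = xc.mean(axis=0)
        sigma[i] = np.sqrt(np.maximum(xc.var(axis=0), var_floor))
    priors = (
        np.full(classes.size, 1.0 / classes.size)
        if uniform_priors
        else counts / counts.sum()
    )
    return GnbModel(classes, priors, mu, sigma)


def gnb_predict(model: GnbModel, x: np.ndarray):
    """Classify frame(s); returns (label(s), posterior(s) summing to 1).

    The product of Gaussian likelihoods is evaluated in log space; the
    argmax breaks ties toward the lowest class index.
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    xb = x[None, :] if single else x
    if xb.shape[1] != model.n_features:
        raise ShapeError(
            f"input has {xb.shape[1]} features, model expects {model.n_features}"
        )
    if not np.all(np.isfinite(xb)):
        raise InvalidParameterError("non-finite values in decoder input")
    # log P(y) + sum_i log N(x_i | mu, sigma)
    log_lik = -0.5 * (
        ((xb[:, None, :] - model.mu[None]) / model.sigma[None]) ** 2
        + 2.0 * np.log(model.sigma[None])
        + np.log(2.0 * np.pi)
    ).sum(axis=2)
    log_post = np.log(model.priors)[None] + log_lik
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    labels = model.classes[np.argmax(post, axis=1)]
    if single:
        return labels[0], post[0]
    return labels, post


# ---------------------------------------------------------------------------
# framing

def make_windows(traces: TraceMatrix | np.ndarray, w: int, labels: Sequence):
    """Sliding windows of W frames (stride 1, valid-only).

    Returns ``(windows, window_labels)`` with windows shaped
    (T - W + 1, W, neurons); each window carries the label of its LAST
    frame so the framing is causal and usable in real time.
    """
    values = traces.values if isinstance(traces, TraceMatrix) else np.asarray(traces)
    labels = np.asarray(labels)
    t = values.shape[1]
    if labels.shape[0] != t:
        raise ShapeError(f"{labels.shape[0]} labels for {t} frames")
    if w < 1:
        raise InvalidParameterError(f"window length must be >= 1, got {w}")
    if t < w:
        raise InsufficientDataError(f"need at least {w} frames, got {t}")
    n_windows = t - w + 1
    # (T-W+1, W, N): stride trick over the frame axis, then copy
    x = np.lib.stride_tricks.sliding_window_view(values, w, axis=1)  # N x n_win x W
    windows = np.ascontiguousarray(np.moveaxis(x, 0, 2))  # n_win x W x N
    return windows, labels[w - 1 :].copy()


@dataclasses.dataclass
class EpochTensor:
    """Stimulus-aligned epochs: epochs x neurons x frames, one label each."""

    values: np.ndarray
    labels: np.ndarray
    fps: float

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def epoch_frames(self) -> int:
        return self.values.shape[2]

    def as_time_major(self) -> np.ndarray:
        """(epochs, frames, neurons) view for temporal models."""
        return np.moveaxis(self.values, 1, 2)


def make_epochs(
    traces: TraceMatrix, schedule: StimulusSchedule, e: int = 150
) -> EpochTensor:
    """Cut one E-frame epoch per stimulus onset, labelled by the stimulus.

    Epochs whose window would run past the end of the recording are
    dropped with a warning.
    """
    if e < 1:
        raise InvalidParameterError(f"epoch length must be >= 1, got {e}")
    onsets = schedule.epoch_onsets()
    if onsets.size == 0:
        raise EmptyResultError("schedule contains no stimulus onsets")
    labels_all = schedule.epoch_labels()
    keep = onsets + e <= traces.n_frames
    if not np.all(keep):
        warnings.warn(f"{int((~keep).sum())} trailing epoch(s) incomplete; dropped")
    onsets, labels = onsets[keep], labels_all[keep]
    if onsets.size == 0:
        raise EmptyResultError("no complete epoch fits inside the recording")
    values = np.stack([traces.values[:, o : o + e] for o in onsets])
    return EpochTensor(values, np.asarray(labels), traces.fps)


# ---------------------------------------------------------------------------
# unified decoder surface

@dataclasses.dataclass
class DecoderModel:
    """A fitted decoder plus everything needed to apply it to a stream."""

    kind: str
    estimator: object
    normalizer: Normalizer | None
    contract: Literal["frame", "window", "epoch"]
    classes: np.ndarray
    cv_results: list[dict]
    best_params: dict
    seed: int
    window: int | None = None  # W for lstm, E for cnn

    def expected_shape(self) -> str:
        if self.contract == "frame":
            return "(features,) or (samples, features)"
        return f"({self.window}, features) or (samples, {self.window}, features)"


def _grid_candidates(kind: str, grid: dict | None) -> list[dict]:
    grid = dict(DEFAULT_GRIDS.get(kind, {})) if grid is None else dict(grid)
    if not grid:
        return [{}]
    keys = sorted(grid)
    # ascending product order puts smaller models first; a tie in CV
    # accuracy therefore resolves toward the smaller/cheaper setting
    combos = [dict(zip(keys, vals)) for vals in itertools.product(*(sorted(grid[k]) for k in keys))]
    return combos


def _make_estimator(kind: str, params: dict, n_features: int, seed: int):
    if kind == "gnb":
        return None  # fitted directly via gnb_fit
    if kind == "svm":
        return SVC(
            kernel="rbf",
            gamma=1.0 / n_features,
            C=params.get("C", 1.0),
            decision_function_shape="ovr",
            random_state=seed,
        )
    if kind == "mlp":
        h = params.get("hidden", 64)
        return MLPClassifier(
            hidden_layer_sizes=(h, h),
            activation="relu",
            solver="adam",
            batch_size=32,
            learning_rate_init=params.get("lr", 1e-3),
            max_iter=params.get("epochs", 50),
            # strong L2 keeps the high-dimensional population input from
            # overfitting a single session's noise realization
            alpha=params.get("alpha", 1.0),
            random_state=seed,
        )
    if kind == "lstm":
        return LSTMClassifier(
            hidden=params.get("hidden", 32),
            lr=params.get("lr", 1e-3),
            epochs=params.get("epochs", 20),
            seed=seed,
        )
    if kind == "cnn":
        return CNNClassifier(
            filters=params.get("filters", 32),
            lr=params.get("lr", 1e-3),
            epochs=params.get("epochs", 20),
            seed=seed,
        )
    raise InvalidParameterError(f"unknown decoder kind {kind!r}")


def _fit_one(kind: str, params: dict, x: np.ndarray, y: np.ndarray, seed: int):
    n_features = x.shape[-1]
    if kind == "gnb":
        return gnb_fit(x, y)
    est = _make_estimator(kind, params, n_features, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(x, y)
    return est


def _predict_labels(kind: str, est, x: np.ndarray) -> np.ndarray:
    if kind == "gnb":
        labels, _ = gnb_predict(est, x)
        return labels
    return est.predict(x)


def train_decoder(
    kind: str,
    x: np.ndarray,
    y: Sequence,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
    normalizer: Normalizer | None = None,
) -> DecoderModel:
    """Grid-search, cross-validate and refit one decoder family.

    ``x`` must already satisfy the family's framing contract: frames x
    features for gnb/svm/mlp, samples x W x features for lstm, samples x E
    x features for cnn.  Inputs for every family except the CNN are
    standardized with a normalizer fit here (or the one supplied);
    the CNN consumes raw intensities.  The best hyperparameters maximize
    mean CV accuracy; ties go to the smaller model (grid is scanned in
    ascending size order with strict improvement required to switch).
    """
    if kind not in DECODER_KINDS:
        raise InvalidParameterError(f"unknown decoder kind {kind!r}; choose from {DECODER_KINDS}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    expected_ndim = 2 if kind in ("gnb", "svm", "mlp") else 3
    if x.ndim != expected_ndim:
        raise ShapeError(
            f"decoder kind {kind!r} expects {expected_ndim}-D input, got {x.ndim}-D"
        )
    if x.shape[0] != y.shape[0]:
        raise ShapeError("x and y must have the same number of samples")
    classes, counts = np.unique(y, return_counts=True)
    lacking = classes[counts < folds]
    if lacking.size:
        raise InsufficientDataError(
            f"classes {lacking.tolist()} have fewer than {folds} samples"
        )

    if kind == "cnn":
        norm = None
        xn = x
    else:
        if normalizer is None:
            flat = x.reshape(-1, x.shape[-1]) if x.ndim == 3 else x
            norm = fit_normalizer(flat)
        else:
            norm = normalizer
        xn = norm.apply(x)

    candidates = _grid_candidates(kind, grid)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    cv_results = []
    best_acc, best_params = -1.0, candidates[0]
    for params in candidates:
        fold_accs = []
        for train_idx, test_idx in splits:
            est = _fit_one(kind, params, xn[train_idx], y[train_idx], seed)
            pred = _predict_labels(kind, est, xn[test_idx])
            fold_accs.append(float(np.mean(pred == y[test_idx])))
        mean_acc = float(np.mean(fold_accs))
        cv_results.append({"params": params, "fold_accuracy": fold_accs, "mean_accuracy": mean_acc})
        if mean_acc > best_acc:  # strict: ties keep the earlier (smaller) model
            best_acc, best_params = mean_acc, params

    est = _fit_one(kind, best_params, xn, y, seed)
    window = x.shape[1] if x.ndim == 3 else None
    return DecoderModel(
        kind=kind,
        estimator=est,
        normalizer=norm,
        contract={"gnb": "frame", "svm": "frame", "mlp": "frame", "lstm": "window", "cnn": "epoch"}[kind],
        classes=classes,
        cv_results=cv_results,
        best_params=best_params,
        seed=seed,
        window=window,
    )


def _scores(kind: str, est, xn: np.ndarray, n_classes: int) -> np.ndarray:
    if kind == "gnb":
        _, post = gnb_predict(est, xn)
        return post
    if kind == "svm":
        df = est.decision_function(xn)
        if df.ndim == 1:  # binary: expand to two columns
            df = np.stack([-df, df], axis=1)
        e = np.exp(df - df.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)
    return est.predict_proba(xn)


def predict(model: DecoderModel, x: np.ndarray):
    """Apply a fitted decoder to one sample or a batch.

    Returns ``(label, scores)`` for a single sample or ``(labels, scores)``
    for a batch; scores are normalized to sum to 1 per sample.
    """
    x = np.asarray(x, dtype=np.float64)
    sample_ndim = 1 if model.contract == "frame" else 2
    single = x.ndim == sample_ndim
    xb = x[None] if single else x
    if xb.ndim != sample_ndim + 1:
        raise ShapeError(
            f"{model.kind} decoder expects input shaped {model.expected_shape()}"
        )
    if model.contract != "frame" and xb.shape[1] != model.window:
        raise ShapeError(
            f"{model.kind} decoder expects {model.window}-frame samples, got {xb.shape[1]}"
        )
    if not np.all(np.isfinite(xb)):
        raise InvalidParameterError("non-finite values in decoder input")
    xn = model.normalizer.apply(xb) if model.normalizer is not None else xb
    if model.kind == "gnb":
        labels, scores = gnb_predict(model.estimator, xn)
    else:
        labels = model.estimator.predict(xn)
        scores = _scores(model.kind, model.estimator, xn, model.classes.size)
    if single:
        return labels[0], scores[0]
    return labels, scores
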