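"""Constant-velocity Kalman filter for decoded positions.

State is [position, velocity] with transition A = [[1, dt], [0, 1]],
control B = [dt^2/2, dt] acting on an (optional) acceleration input, and
scalar observation H = [1, 0] of the decoded bin center.  Process noise is
Q * I_2 and observation noise R, with the defaults Q = 1e-4, R = 1 at
dt = 1/30 s.  The filter starts from zero state with unit covariance.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import KalmanSettings
from .errors import InvalidParameterError

__all__ = ["KalmanConfig", "KalmanState", "kalman_step", "kalman_filter"]


@dataclasses.dataclass(frozen=True)
class KalmanConfig:
    dt: float = 1.0 / 30.0
    q: float = 1e-4
    r: float = 1.0
    u: float = 0.0  # control acceleration (cm/s^2); 0 = pure constant-velocity

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        if self.q <= 0 or self.r <= 0:
            raise InvalidParameterError("q and r must be > 0")

    @property
    def a(self) -> np.ndarray:
        return np.array([[1.0, self.dt], [0.0, 1.0]])

    @property
    def b(self) -> np.ndarray:
        return np.array([0.5 * self.dt**2, self.dt])

    @property
    def h(self) -> np.ndarray:
        return np.array([1.0, 0.0])

    @classmethod
    def from_settings(cls, s: KalmanSettings, u: float = 0.0) -> "KalmanConfig":
        return cls(dt=s.dt, q=s.q, r=s.r, u=u)


@dataclasses.dataclass
class KalmanState:
    x: np.ndarray  # [position, velocity]
    p: np.ndarray  # 2x2 estimate covariance
    k: np.ndarray | None = None  # last Kalman gain

    @classmethod
    def initial(cls) -> "KalmanState":
        """Zero state, identity covariance."""
        return cls(np.zeros(2), np.eye(2))


def kalman_step(state: KalmanState, z: float, config: KalmanConfig) -> KalmanState:
    """One predict/update cycle on a scalar position measurement ``z`` (cm).

    A non-finite measurement triggers prediction-only (skip-update) mode.
    """
    a, b, h = config.a, config.b, config.h
    # time update
    x_prior = a @ state.x + b * config.u
    p_prior = a @ state.p @ a.T + config.q * np.eye(2)
    if not np.isfinite(z):
        import warnings

        warnings.warn("non-finite measurement; Kalman update skipped (prediction only)")
        return KalmanState(x_prior, 0.5 * (p_prior + p_prior.T), state.k)
    # measurement update
    s = float(h @ p_prior @ h) + config.r
    k = (p_prior @ h) / s
    x_post = x_prior + k * (z - float(h @ x_prior))
    p_post = (np.eye(2) - np.outer(k, h)) @ p_prior
    p_post = 0.5 * (p_post + p_post.T)  # enforce symmetry against roundoff
    return KalmanState(x_post, p_post, k)


def kalman_filter(
    measurements: np.ndarray,
    config: KalmanConfig | None = None,
    track_length_cm: float | None = None,
    return_states: bool = False,
):
    """Filter a sequence of decoded positions (cm).

    Runs :func:`kalman_step` sequentially from the zero/identity initial
    state and returns the filtered positions (H x), clipped to
    ``[0, track_length_cm]`` when a track length is given; the internal
    state is never clipped.
    """
    config = config or KalmanConfig()
    measurements = np.asarray(measurements, dtype=np.float64)
    if measurements.ndim != 1:
        raise InvalidParameterError("measurements must be a 1-D sequence")
    state = KalmanState.initial()
    out = np.empty(measurements.size)
    states = []
    for i, z in enumerate(measurements):
        state = kalman_step(state, float(z), config)
        out[i] = state.x[0]
        if return_states:
            states.append(state)
    if track_length_cm is not None:
        out = np.clip(out, 0.0, track_length_cm)
    if return_states:
        return out, states
    return out
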