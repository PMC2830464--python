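"""Optimal linear filter: sliding-window multiple regression decoder.

A response matrix stacks, for each timestep t >= L-1, the spike counts of
the last L timesteps across all neurons (window length L, default 4) plus an
intercept column.  Training fits separate x- and y-velocity filters by
multiple regression, f = (R^T R)^-1 R^T v, against the velocity at the end
of each window; decoding multiplies new response rows by the filters.  The
window spans L timesteps of history, so the first L-1 estimates are
undefined and are padded with the first valid prediction to keep every
decoder on the same timeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..errors import InputError, ParameterError, TrainingError
from ..synthetic import SpikeCountMatrix, VelocitySeries
from .base import DecoderEstimate

__all__ = ["LinearFilterModel", "build_response_matrix", "train_linear", "decode_linear"]

#: relative condition number beyond which the normal equations get a ridge
_COND_LIMIT = 1e10


@dataclass
class LinearFilterModel:
    """Trained sliding-window regression filters for v_x and v_y."""

    window_length: int
    coef: np.ndarray  # (n_neurons * L + intercept, 2) columns: f_x, f_y
    n_neurons: int
    include_intercept: bool = True
    delay: int = None  # window extent in timesteps

    def __post_init__(self):
        if self.delay is None:
            self.delay = self.window_length
        expected = self.n_neurons * self.window_length + int(self.include_intercept)
        if self.coef.shape != (expected, 2):
            raise InputError(
                f"coefficient shape {self.coef.shape} inconsistent with "
                f"L={self.window_length}, {self.n_neurons} neurons")


def build_response_matrix(
    spikes: SpikeCountMatrix, L: int, include_intercept: bool = True
) -> np.ndarray:
    """Stack sliding windows of counts into regression rows.

    Row j (for t = L-1+j) concatenates ``counts[t-L+1 .. t]`` across neurons
    in time order, oldest first, plus a trailing column of ones.  Shape:
    (n_steps - L + 1, n_neurons * L + 1).
    """
    if L < 1:
        raise ParameterError(f"window length must be >= 1, got {L}")
    counts = np.asarray(spikes.counts, dtype=float)
    n_steps, n_neurons = counts.shape
    if n_steps < L:
        raise InputError(f"need at least L={L} timesteps, got {n_steps}")
    # windows[j, k, i] = counts[j + k, i]; flatten time-major so each window
    # is [step t-L+1 all neurons, ..., step t all neurons]
    windows = np.lib.stride_tricks.sliding_window_view(counts, L, axis=0)  # (rows, neurons, L)
    R = windows.transpose(0, 2, 1).reshape(n_steps - L + 1, n_neurons * L)
    if include_intercept:
        R = np.hstack([R, np.ones((R.shape[0], 1))])
    return R


def _solve_normal_equations(R: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """f = (R^T R)^-1 R^T v, with a loud ridge fallback on rank deficiency."""
    G = R.T @ R
    if R.shape[0] < R.shape[1] or np.linalg.matrix_rank(G) < G.shape[0] \
            or np.linalg.cond(G) > _COND_LIMIT:
        penalty = 1e-8 * np.trace(G) / G.shape[0]
        if penalty <= 0:
            raise TrainingError("response matrix is identically zero; nothing to fit")
        warnings.warn(
            f"response matrix rank-deficient or ill-conditioned; applying ridge "
            f"penalty {penalty:.3e}",
            RuntimeWarning,
            stacklevel=3,
        )
        G = G + penalty * np.eye(G.shape[0])
    return np.linalg.solve(G, R.T @ targets)


def train_linear(
    spikes: SpikeCountMatrix,
    vel: VelocitySeries,
    L: int = 4,
    include_intercept: bool = True,
) -> LinearFilterModel:
    """Multiple regression of window-end velocities on the response matrix."""
    if spikes.n_steps != len(vel):
        raise InputError("spikes and velocities misaligned")
    R = build_response_matrix(spikes, L, include_intercept)
    targets = vel.velocities[L - 1:]
    coef = _solve_normal_equations(R, targets)
    return LinearFilterModel(
        window_length=L, coef=coef, n_neurons=spikes.n_neurons,
        include_intercept=include_intercept,
    )


def decode_linear(model: LinearFilterModel, spikes: SpikeCountMatrix) -> DecoderEstimate:
    """Predict velocities; pad the leading window gap with the first estimate."""
    if spikes.n_neurons != model.n_neurons:
        raise InputError(
            f"spike matrix has {spikes.n_neurons} neurons, model expects {model.n_neurons}")
    L = model.window_length
    R = build_response_matrix(spikes, L, model.include_intercept)
    pred = R @ model.coef  # aligned to t = L-1 .. n_steps-1
    pad = np.repeat(pred[:1], L - 1, axis=0)
    return DecoderEstimate(decoder_id="linear", velocities=np.vstack([pad, pred]))
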