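"""Linear-Gaussian state-space decoding with closed-form training.

The state model is ``x_k = A x_{k-1} + w_k``, ``w_k ~ N(0, W)``; the
observation model is ``y_k = H x_k + q_k``, ``q_k ~ N(0, Q)``, with A, W, H,
Q time-invariant.  Given paired training sequences the maximum joint
probability estimates are ordinary least squares:

    A = (sum_k x_k x_{k-1}^T)(sum_k x_{k-1} x_{k-1}^T)^-1
    H = (sum_k y_k x_k^T)(sum_k x_k x_k^T)^-1

with W and Q the covariances of the corresponding residuals.  The same code
path serves the individual spike decoder (observations = spike counts, d_obs
= n_neurons) and the fusion filter (observations = stacked decoder
estimates, d_obs = 2 * n_decoders); only the observation source differs.

Spike counts have a nonzero baseline, so by default observations (and
states) are mean-centered before fitting; the offsets are stored on the
model and reapplied when filtering.  Set ``center=False`` to fit the raw
printed formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ..errors import FilteringError, InputError, TrainingError
from ..synthetic import SpikeCountMatrix, Trajectory, VelocitySeries
from .base import DecoderEstimate

__all__ = ["KalmanModel", "train_kalman", "kalman_filter", "decode_kalman"]

#: state layouts: name -> column labels
_STATE_LAYOUTS = {
    "velocity": ("vx", "vy"),
    "position_velocity": ("x", "y", "vx", "vy"),
}


@dataclass
class KalmanModel:
    """Trained linear-Gaussian state-space model.

    ``state_mean``/``obs_mean`` are the training means subtracted before
    fitting (zero vectors when ``center=False``); filtering works in the
    centered frame and adds ``state_mean`` back.
    """

    A: np.ndarray  # (d_state, d_state)
    W: np.ndarray  # (d_state, d_state)
    H: np.ndarray  # (d_obs, d_state)
    Q: np.ndarray  # (d_obs, d_obs)
    x0: np.ndarray  # (d_state,) initial state mean, centered frame
    P0: np.ndarray  # (d_state, d_state)
    state_mean: np.ndarray
    obs_mean: np.ndarray
    state_labels: tuple[str, ...] = ("vx", "vy")
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        d = self.A.shape[0]
        m = self.H.shape[0]
        if self.A.shape != (d, d) or self.W.shape != (d, d) or self.H.shape != (m, d) \
                or self.Q.shape != (m, m) or self.x0.shape != (d,) or self.P0.shape != (d, d):
            raise InputError("inconsistent Kalman model dimensions")

    @property
    def d_state(self) -> int:
        return self.A.shape[0]

    @property
    def d_obs(self) -> int:
        return self.H.shape[0]


def _ls_rows(name: str, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Solve ``Y ~= X B`` by least squares and return ``B^T`` (rows map x->y).

    Raises :class:`TrainingError` when the design is identically zero;
    warns and returns the minimum-norm solution when merely rank-deficient.
    """
    if not np.any(X):
        raise TrainingError(f"degenerate training data: {name} design matrix is all zeros")
    B, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"{name} design matrix is rank-deficient (rank {rank} < {X.shape[1]}); "
            "using the minimum-norm solution",
            RuntimeWarning,
            stacklevel=3,
        )
    return B.T


def train_kalman(
    spikes: SpikeCountMatrix,
    vel: VelocitySeries,
    *,
    positions: Trajectory | np.ndarray | None = None,
    state: str = "velocity",
    center: bool = True,
) -> KalmanModel:
    """Closed-form maximum joint probability training on paired sequences.

    Parameters
    ----------
    spikes : observations, one row per timestep.
    vel : true velocities aligned with ``spikes``.
    positions : required when ``state='position_velocity'``; positions whose
        first differences produced ``vel`` (one extra row).
    state : ``'velocity'`` (default, 2-D state) or ``'position_velocity'``.
    center : subtract training means before fitting (recommended: spike
        counts have a nonzero baseline the H x term cannot absorb).
    """
    return _train_statespace(np.asarray(spikes.counts, dtype=float), vel,
                             positions=positions, state=state, center=center)


def _train_statespace(
    Y: np.ndarray,
    vel: VelocitySeries,
    *,
    positions=None,
    state: str = "velocity",
    center: bool = True,
) -> KalmanModel:
    if state not in _STATE_LAYOUTS:
        raise InputError(f"unknown state layout {state!r}")
    V = vel.velocities
    n = V.shape[0]
    if Y.shape[0] != n:
        raise InputError(f"observations ({Y.shape[0]} rows) and velocities ({n}) misaligned")
    if n < 2:
        raise InputError("need at least 2 timesteps to train")

    if state == "velocity":
        X = V
    else:
        if positions is None:
            raise InputError("state='position_velocity' requires positions")
        pos = positions.positions if isinstance(positions, Trajectory) else np.asarray(positions, float)
        if pos.shape[0] != n + 1:
            raise InputError("positions must have one more row than velocities")
        X = np.hstack([pos[1:], V])

    x_mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    y_mean = Y.mean(axis=0) if center else np.zeros(Y.shape[1])
    Xc = X - x_mean
    Yc = Y - y_mean

    A = _ls_rows("state-transition", Xc[:-1], Xc[1:])
    res_w = Xc[1:] - Xc[:-1] @ A.T
    W = res_w.T @ res_w / max(n - 1, 1)

    H = _ls_rows("observation", Xc, Yc)
    res_q = Yc - Xc @ H.T
    Q = res_q.T @ res_q / n

    return KalmanModel(
        A=A, W=W, H=H, Q=Q,
        x0=np.zeros(X.shape[1]), P0=W.copy(),
        state_mean=x_mean, obs_mean=y_mean,
        state_labels=_STATE_LAYOUTS[state],
        meta={"n_train": int(n), "centered": bool(center)},
    )


def kalman_filter(model: KalmanModel, observations: np.ndarray) -> np.ndarray:
    """Run the standard predict/update recursion over observation rows.

    Predict: x- = A x, P- = A P A^T + W.
    Update:  K = P- H^T (H P- H^T + Q)^-1; x = x- + K (y - H x-).

    Observations are given in raw units; the stored means are applied
    internally.  Returns the filtered state means, one row per observation,
    in raw (uncentered) units.
    """
    Y = np.asarray(observations, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if Y.shape[1] != model.d_obs:
        raise InputError(f"observation dimension {Y.shape[1]} != model d_obs {model.d_obs}")
    Yc = Y - model.obs_mean

    A, W, H, Q = model.A, model.W, model.H, model.Q
    x = model.x0.copy()
    P = model.P0.copy()
    out = np.empty((Y.shape[0], model.d_state))
    for t in range(Y.shape[0]):
        x = A @ x
        P = A @ P @ A.T + W
        S = H @ P @ H.T + Q
        try:
            c, low = scipy.linalg.cho_factor(S, check_finite=False)
            # K^T = S^-1 H P  (S symmetric)
            KT = scipy.linalg.cho_solve((c, low), H @ P, check_finite=False)
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError) as exc:
            raise FilteringError(
                f"innovation covariance numerically singular at step {t}; "
                "consider regularizing Q (e.g. add a small multiple of the identity)"
            ) from exc
        K = KT.T
        x = x + K @ (Yc[t] - H @ x)
        P = P - K @ H @ P
        P = 0.5 * (P + P.T)  # keep symmetric
        out[t] = x
    return out + model.state_mean


def decode_kalman(model: KalmanModel, spikes: SpikeCountMatrix) -> DecoderEstimate:
    """Filter a spike-count matrix and return the velocity components."""
    if spikes.n_neurons != model.d_obs:
        raise InputError(f"spike matrix has {spikes.n_neurons} neurons, model expects {model.d_obs}")
    states = kalman_filter(model, np.asarray(spikes.counts, dtype=float))
    vx = model.state_labels.index("vx")
    return DecoderEstimate(decoder_id="kalman", velocities=states[:, vx:vx + 2])
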