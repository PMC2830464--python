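"""Population-vector-style decoder built on the cosine-tuning model.

Each neuron's mean count is modeled as

    E[y_t] = a0 + ap * v_t * cos(theta_t - theta_p)
           = a0 + cx * v_x(t) + cy * v_y(t),   (cx, cy) = ap * (cos, sin)(theta_p)

so only three parameters per neuron need estimating.  Fitting runs
Gauss-Newton (iterated first-order Taylor linearization) on the nonlinear
(a0, ap, theta_p) parametrization, initialized from the closed-form OLS
solution in the linear (a0, cx, cy) coordinates — to which it is equivalent
at the optimum.  Decoding solves, per timestep, the overdetermined linear
system ``counts_t - a0 = C @ (v_x, v_y)`` across neurons by least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..errors import DecodingError, InputError, TrainingError
from ..synthetic import SpikeCountMatrix, VelocitySeries
from .base import DecoderEstimate

__all__ = ["PVAModel", "train_pva", "decode_pva"]


@dataclass
class PVAModel:
    """Per-neuron tuning estimates in both parametrizations plus fit diagnostics.

    ``unidentifiable`` marks neurons whose fitted modulation depth is not
    distinguishable from zero (ap below ~3 standard errors), for which
    ``theta_p`` carries no information.
    """

    a0: np.ndarray
    ap: np.ndarray  # >= 0; theta_p absorbs sign
    theta_p: np.ndarray
    cx: np.ndarray
    cy: np.ndarray
    iterations: np.ndarray  # Gauss-Newton iterations per neuron
    rss: np.ndarray  # final residual sum of squares per neuron
    unidentifiable: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.unidentifiable is None:
            self.unidentifiable = self.ap < 1e-9

    @property
    def n_neurons(self) -> int:
        return self.a0.shape[0]


def _gauss_newton_neuron(y, v, theta, a0, ap, th, max_iter, tol):
    """Refine (a0, ap, theta_p) for one neuron; returns params, iters, rss."""
    def rss_of(p):
        r = y - (p[0] + p[1] * v * np.cos(theta - p[2]))
        return float(r @ r)

    p = np.array([a0, ap, th], dtype=float)
    best = rss_of(p)
    it = 0
    for it in range(1, max_iter + 1):
        c = np.cos(theta - p[2])
        s = np.sin(theta - p[2])
        r = y - (p[0] + p[1] * v * c)
        # Jacobian of the model wrt (a0, ap, theta_p)
        J = np.column_stack([np.ones_like(v), v * c, p[1] * v * s])
        try:
            step, *_ = np.linalg.lstsq(J, r, rcond=None)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        # step halving on residual increase
        scale = 1.0
        new = p + step
        new_rss = rss_of(new)
        while new_rss > best and scale > 1e-8:
            scale *= 0.5
            new = p + scale * step
            new_rss = rss_of(new)
        if new_rss > best:
            break
        moved = float(np.max(np.abs(new - p)))
        p, best = new, new_rss
        if moved < tol:
            break
    # canonicalize: ap >= 0, theta_p in [-pi, pi]
    if p[1] < 0:
        p[1] = -p[1]
        p[2] += np.pi
    p[2] = np.arctan2(np.sin(p[2]), np.cos(p[2]))
    return p, it, best


def train_pva(
    spikes: SpikeCountMatrix,
    vel: VelocitySeries,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> PVAModel:
    """Fit per-neuron cosine-tuning parameters.

    OLS in the linearized (a0, cx, cy) coordinates seeds a per-neuron
    Gauss-Newton refinement in (a0, ap, theta_p) with step halving.  A
    rank-deficient design (e.g. movement confined to a line) triggers a
    warning and falls back to the minimum-norm OLS coordinates.
    """
    Y = np.asarray(spikes.counts, dtype=float)
    V = vel.velocities
    if Y.shape[0] != V.shape[0]:
        raise InputError("spikes and velocities misaligned")
    if Y.shape[0] < 3:
        raise InputError("need at least 3 timesteps to fit 3 parameters per neuron")
    v = vel.speed
    theta = vel.angle

    M = np.column_stack([np.ones_like(v), V[:, 0], V[:, 1]])
    if not np.any(M[:, 1:]):
        raise TrainingError("degenerate training data: all velocities are zero")
    beta, _, rank, _ = np.linalg.lstsq(M, Y, rcond=None)  # (3, n_neurons)
    rank_deficient = rank < 3
    if rank_deficient:
        warnings.warn(
            "velocity design is rank-deficient (movement confined to a line?); "
            "keeping minimum-norm OLS tuning coordinates",
            RuntimeWarning,
            stacklevel=2,
        )

    n_neurons = Y.shape[1]
    a0 = beta[0].copy()
    cx = beta[1].copy()
    cy = beta[2].copy()
    ap = np.hypot(cx, cy)
    th = np.arctan2(cy, cx)
    iters = np.zeros(n_neurons, dtype=int)
    rss = np.empty(n_neurons)

    for i in range(n_neurons):
        if rank_deficient:
            r = Y[:, i] - M @ beta[:, i]
            rss[i] = float(r @ r)
            continue
        p, it, best = _gauss_newton_neuron(Y[:, i], v, theta, a0[i], ap[i], th[i], max_iter, tol)
        a0[i], ap[i], th[i] = p
        iters[i] = it
        rss[i] = best
        cx[i] = ap[i] * np.cos(th[i])
        cy[i] = ap[i] * np.sin(th[i])

    # identifiability: ap below ~3 standard errors of the (cx, cy) estimate
    # (Gaussian-approximation covariance of the shared linearized design)
    dof = max(Y.shape[0] - 3, 1)
    sigma2 = rss / dof
    gram_inv = np.linalg.pinv(M.T @ M)
    se_c = np.sqrt(np.clip(sigma2 * (gram_inv[1, 1] + gram_inv[2, 2]), 0.0, None))
    unidentifiable = ap <= 3.0 * se_c + 1e-12

    model = PVAModel(a0=a0, ap=ap, theta_p=th, cx=cx, cy=cy, iterations=iters,
                     rss=rss, unidentifiable=unidentifiable)
    if np.any(model.unidentifiable):
        flagged = np.flatnonzero(model.unidentifiable).tolist()
        warnings.warn(
            f"neurons {flagged} have ~zero modulation depth; their preferred "
            "directions are unidentifiable",
            RuntimeWarning,
            stacklevel=2,
        )
    return model


def decode_pva(model: PVAModel, spikes: SpikeCountMatrix) -> DecoderEstimate:
    """Least-squares velocity estimate per timestep from baseline-subtracted counts."""
    if spikes.n_neurons != model.n_neurons:
        raise InputError(
            f"spike matrix has {spikes.n_neurons} neurons, model expects {model.n_neurons}")
    if model.n_neurons < 3:
        raise InputError("decoding requires at least 3 neurons")
    C = np.column_stack([model.cx, model.cy])  # (n_neurons, 2)
    G = C.T @ C
    if np.linalg.matrix_rank(G) < 2 or np.linalg.cond(G) > 1e12:
        raise DecodingError("tuning coefficients are collinear; velocity is not recoverable")
    B = np.asarray(spikes.counts, dtype=float) - model.a0[None, :]
    V = np.linalg.solve(G, C.T @ B.T).T
    return DecoderEstimate(decoder_id="pva", velocities=V)
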