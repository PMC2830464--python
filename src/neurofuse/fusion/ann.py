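"""Feed-forward ANN fusion: tansigmoid hidden layers, linear output, SCG training.

Networks have one or two fully-connected hidden layers.  At each timestep
the stacked individual-decoder estimates feed the input units and the two
linear output units produce the fused (v_x, v_y).  Inputs are z-scored with
training-set statistics; targets are left raw.  Training minimizes
mean-squared error with scaled conjugate gradient, and a validation series
provides early stopping: the returned weights belong to the epoch with the
lowest validation MSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..decoders.base import DecoderEstimate
from ..errors import InputError, ParameterError
from ..synthetic import VelocitySeries
from .observations import FusionObservationSeries
from .scg import scg_minimize

__all__ = ["ANNTopology", "ANNModel", "ann_forward", "train_ann", "decode_ann"]

N_OUTPUTS = 2


@dataclass(frozen=True)
class ANNTopology:
    """Hidden-layer sizes: h2 = 0 means a single hidden layer."""

    h1: int
    h2: int = 0

    def __post_init__(self):
        if self.h1 < 1:
            raise ParameterError(f"first hidden layer needs >= 1 unit, got {self.h1}")
        if self.h2 < 0:
            raise ParameterError(f"second hidden layer size must be >= 0, got {self.h2}")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.h1,) if self.h2 == 0 else (self.h1, self.h2)


@dataclass
class ANNModel:
    """Trained fusion network: weights, normalization constants, training log."""

    topology: ANNTopology
    weights: list[np.ndarray]  # per layer, shape (fan_in, fan_out)
    biases: list[np.ndarray]  # per layer, shape (fan_out,)
    input_mean: np.ndarray
    input_sd: np.ndarray
    train_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    val_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    best_epoch: int = 0

    def __post_init__(self):
        sizes = (self.input_mean.shape[0], *self.topology.layer_sizes, N_OUTPUTS)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape != (sizes[i], sizes[i + 1]) or b.shape != (sizes[i + 1],):
                raise InputError(f"layer {i} weight shapes inconsistent with topology")
        if np.any(self.input_sd <= 0):
            raise InputError("input normalization sd must be positive")

    @property
    def n_inputs(self) -> int:
        return self.input_mean.shape[0]


def _as_matrix(obs) -> np.ndarray:
    if isinstance(obs, FusionObservationSeries):
        return obs.observations
    return np.asarray(obs, dtype=float)


def _as_targets(vel) -> np.ndarray:
    if isinstance(vel, VelocitySeries):
        return vel.velocities
    return np.asarray(vel, dtype=float)


def ann_forward(model: ANNModel, obs: np.ndarray) -> np.ndarray:
    """Forward pass; accepts a single observation row or a matrix."""
    X = _as_matrix(obs)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.n_inputs:
        raise InputError(f"input dimension {X.shape[1]} != model inputs {model.n_inputs}")
    a = (X - model.input_mean) / model.input_sd
    for W, b in zip(model.weights[:-1], model.biases[:-1]):
        a = np.tanh(a @ W + b)
    out = a @ model.weights[-1] + model.biases[-1]
    return out[0] if single else out


def decode_ann(model: ANNModel, obs: FusionObservationSeries) -> DecoderEstimate:
    """Run the network over an observation series."""
    return DecoderEstimate(decoder_id="ann_fusion", velocities=ann_forward(model, obs))


# ---------------------------------------------------------------------------
# training


def _layer_sizes(n_inputs: int, topology: ANNTopology) -> tuple[int, ...]:
    return (n_inputs, *topology.layer_sizes, N_OUTPUTS)


def _init_layers(sizes, rng) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(rng.uniform(-bound, bound, size=fan_out))
    return weights, biases


def _pack(weights, biases) -> np.ndarray:
    return np.concatenate([a.ravel() for pair in zip(weights, biases) for a in pair])


def _unpack(w: np.ndarray, sizes) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    off = 0
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(w[off:off + fan_in * fan_out].reshape(fan_in, fan_out))
        off += fan_in * fan_out
        biases.append(w[off:off + fan_out])
        off += fan_out
    return weights, biases


def _mse_and_grad(w, sizes, X, T):
    """Mean squared error over all output elements and its weight gradient."""
    weights, biases = _unpack(w, sizes)
    acts = [X]
    a = X
    for W, b in zip(weights[:-1], biases[:-1]):
        a = np.tanh(a @ W + b)
        acts.append(a)
    pred = a @ weights[-1] + biases[-1]
    err = pred - T
    n_el = err.size
    loss = float(np.sum(err * err)) / n_el

    g_w = [None] * len(weights)
    g_b = [None] * len(biases)
    delta = 2.0 * err / n_el
    for layer in range(len(weights) - 1, -1, -1):
        g_w[layer] = acts[layer].T @ delta
        g_b[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ weights[layer].T) * (1.0 - acts[layer] ** 2)
    return loss, _pack(g_w, g_b)


def _mse(w, sizes, X, T) -> float:
    weights, biases = _unpack(w, sizes)
    a = X
    for W, b in zip(weights[:-1], biases[:-1]):
        a = np.tanh(a @ W + b)
    err = a @ weights[-1] + biases[-1] - T
    return float(np.sum(err * err)) / err.size


def train_ann(
    train_obs,
    train_vel,
    val_obs,
    val_vel,
    topology: ANNTopology,
    seed: int = 0,
    max_epochs: int = 500,
    patience: int = 15,
    n_restarts: int = 3,
) -> ANNModel:
    """SCG training with validation early stopping and random restarts.

    One epoch is one successful SCG weight update on the full training batch.
    Training stops after ``patience`` epochs without a new validation-MSE
    minimum, or at ``max_epochs``; the returned weights are those of the best
    validation epoch.  ``n_restarts`` independent initializations (seeds
    derived from ``seed``) are trained and the one with the lowest validation
    MSE wins, which guards against unlucky weight draws.  Deterministic given
    ``seed``.
    """
    if n_restarts < 1:
        raise ParameterError(f"n_restarts must be >= 1, got {n_restarts}")
    Xv = _as_matrix(val_obs)
    Tv = _as_targets(val_vel)
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    for child in children:
        model = _train_ann_once(train_obs, train_vel, val_obs, val_vel, topology,
                                rng=np.random.default_rng(child),
                                max_epochs=max_epochs, patience=patience)
        val_mse = float(np.mean((ann_forward(model, Xv) - Tv) ** 2))
        if best is None or val_mse < best[0]:
            best = (val_mse, model)
    return best[1]


def _train_ann_once(
    train_obs, train_vel, val_obs, val_vel, topology, rng, max_epochs, patience
) -> ANNModel:
    X = _as_matrix(train_obs)
    T = _as_targets(train_vel)
    Xv = _as_matrix(val_obs)
    Tv = _as_targets(val_vel)
    if X.shape[0] != T.shape[0] or Xv.shape[0] != Tv.shape[0]:
        raise InputError("observations and targets misaligned")
    if X.shape[1] != Xv.shape[1]:
        raise InputError("training and validation input dimensions differ")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns stay constant after z-scoring
    Xn = (X - mean) / sd
    Xvn = (Xv - mean) / sd

    sizes = _layer_sizes(X.shape[1], topology)
    w0 = _pack(*_init_layers(sizes, rng))

    train_curve: list[float] = []
    val_curve: list[float] = []
    state = {
        "best_val": _mse(w0, sizes, Xvn, Tv),
        "best_w": w0.copy(),
        "best_epoch": 0,
        "since_best": 0,
    }

    def on_iterate(k, w, f):
        train_curve.append(f)
        val_mse = _mse(w, sizes, Xvn, Tv)
        val_curve.append(val_mse)
        if val_mse < state["best_val"]:
            state["best_val"] = val_mse
            state["best_w"] = w.copy()
            state["best_epoch"] = len(val_curve)
            state["since_best"] = 0
        else:
            state["since_best"] += 1
        return state["since_best"] >= patience

    scg_minimize(lambda w: _mse_and_grad(w, sizes, Xn, T), w0,
                 max_iter=max_epochs, on_iterate=on_iterate)

    weights, biases = _unpack(state["best_w"], sizes)
    return ANNModel(
        topology=topology,
        weights=[W.copy() for W in weights],
        biases=[b.copy() for b in biases],
        input_mean=mean,
        input_sd=sd,
        train_curve=np.asarray(train_curve),
        val_curve=np.asarray(val_curve),
        best_epoch=state["best_epoch"],
    )
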