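"""Synthetic 2-D endpoint trajectories and cosine-tuned Poisson spike counts.

Trajectories are smooth random curves: each coordinate is an independent sum
of sinusoids with uniformly sampled amplitude, angular frequency and phase,
globally rescaled so the mean speed hits a configured target.  Low sampled
frequencies give near-linear paths, high frequencies strongly nonlinear ones,
so a population of trajectories spans both regimes.

Spike counts follow the classic cosine-tuning model: neuron *i* at timestep
*t* fires with Poisson mean

    z[t, i] = max(0, a0_i + ap_i * v_t * cos(theta_t - theta_p_i))

where ``v_t`` and ``theta_t`` are the speed and movement angle and
``theta_p_i`` the neuron's preferred direction.  Negative means are clipped
at zero before sampling.  Time is unitless; velocities are first differences
of positions per timestep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError

__all__ = [
    "TrajectoryParams",
    "Trajectory",
    "VelocitySeries",
    "NeuronTuning",
    "SpikeCountMatrix",
    "generate_trajectory",
    "differentiate",
    "sample_population",
    "tuning_mean",
    "simulate_spikes",
]


def _check_interval(name: str, iv) -> tuple[float, float]:
    try:
        lo, hi = float(iv[0]), float(iv[1])
    except (TypeError, ValueError, IndexError) as exc:
        raise ParameterError(f"{name} must be a (lo, hi) pair, got {iv!r}") from exc
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ParameterError(f"{name} bounds must be finite, got {iv!r}")
    if lo > hi:
        raise ParameterError(f"{name} lower bound {lo} exceeds upper bound {hi}")
    return lo, hi


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of the random sum-of-sinusoids trajectory generator.

    Attributes
    ----------
    n_steps : number of position samples (>= 2).
    n_harmonics : sinusoidal components per coordinate (>= 1).
    amplitude_range, frequency_range, phase_range : closed intervals the
        per-harmonic amplitude, angular frequency (radians per timestep) and
        phase are drawn from, uniformly and independently.
    speed_scale : target mean speed after global rescaling (> 0).
    seed : integer seed; the generator is a pure function of (params, seed).
    """

    n_steps: int = 3001
    n_harmonics: int = 64
    amplitude_range: tuple[float, float] = (0.5, 2.0)
    frequency_range: tuple[float, float] = (0.01, 0.8)
    phase_range: tuple[float, float] = (0.0, 2.0 * np.pi)
    speed_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if int(self.n_steps) < 2:
            raise ParameterError(f"n_steps must be >= 2, got {self.n_steps}")
        if int(self.n_harmonics) < 1:
            raise ParameterError(f"n_harmonics must be >= 1, got {self.n_harmonics}")
        for name in ("amplitude_range", "frequency_range", "phase_range"):
            _check_interval(name, getattr(self, name))
        if not (float(self.speed_scale) > 0):
            raise ParameterError(f"speed_scale must be > 0, got {self.speed_scale}")


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered 2-D endpoint positions (arbitrary length units).

    ``harmonics`` records the sampled generator parameters (after global
    rescaling) for provenance and smoothness bounds; it is ``None`` for
    trajectories read back from disk.
    """

    positions: np.ndarray  # (n_steps, 2)
    harmonics: dict | None = field(default=None, compare=False)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise InputError(f"positions must have shape (n, 2), got {pos.shape}")
        if pos.shape[0] < 2:
            raise InputError("a trajectory needs at least 2 positions")
        if not np.all(np.isfinite(pos)):
            raise InputError("positions contain non-finite values")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class VelocitySeries:
    """Per-timestep 2-D velocities (length units per timestep)."""

    velocities: np.ndarray  # (n, 2)

    def __post_init__(self):
        vel = np.asarray(self.velocities, dtype=float)
        if vel.ndim != 2 or vel.shape[1] != 2:
            raise InputError(f"velocities must have shape (n, 2), got {vel.shape}")
        if not np.all(np.isfinite(vel)):
            raise InputError("velocities contain non-finite values")
        object.__setattr__(self, "velocities", vel)

    def __len__(self) -> int:
        return self.velocities.shape[0]

    @property
    def speed(self) -> np.ndarray:
        """Per-timestep speed ||(v_x, v_y)||."""
        return np.hypot(self.velocities[:, 0], self.velocities[:, 1])

    @property
    def angle(self) -> np.ndarray:
        """Per-timestep movement angle atan2(v_y, v_x), radians in [-pi, pi]."""
        return np.arctan2(self.velocities[:, 1], self.velocities[:, 0])


@dataclass(frozen=True)
class NeuronTuning:
    """Per-neuron cosine-tuning parameters.

    theta_p : preferred direction, radians in [-pi, pi].
    a0 : baseline rate, counts per timestep (>= 0).
    ap : modulation depth, counts per timestep per unit speed.
    """

    theta_p: np.ndarray
    a0: np.ndarray
    ap: np.ndarray

    def __post_init__(self):
        theta_p = np.asarray(self.theta_p, dtype=float)
        a0 = np.asarray(self.a0, dtype=float)
        ap = np.asarray(self.ap, dtype=float)
        if not (theta_p.shape == a0.shape == ap.shape) or theta_p.ndim != 1:
            raise InputError("theta_p, a0, ap must be 1-D arrays of equal length")
        if np.any(a0 < 0):
            raise ParameterError("baseline rates a0 must be nonnegative")
        if np.any(np.abs(theta_p) > np.pi + 1e-12):
            raise ParameterError("preferred directions must lie in [-pi, pi]")
        object.__setattr__(self, "theta_p", theta_p)
        object.__setattr__(self, "a0", a0)
        object.__setattr__(self, "ap", ap)

    @property
    def n_neurons(self) -> int:
        return self.theta_p.shape[0]


@dataclass(frozen=True)
class SpikeCountMatrix:
    """Non-negative integer spike counts, one row per timestep, one column per neuron."""

    counts: np.ndarray  # (n_steps, n_neurons) int

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise InputError(f"counts must be 2-D, got shape {counts.shape}")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise InputError("spike counts must be integer-valued")
            counts = rounded.astype(np.int64)
        if np.any(counts < 0):
            raise InputError("spike counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))

    @property
    def n_steps(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]


def generate_trajectory(params: TrajectoryParams) -> Trajectory:
    """Draw one smooth random trajectory.

    Each coordinate is ``sum_k A_k * sin(w_k * t + phi_k)``; positions are
    then globally rescaled so the mean step speed equals
    ``params.speed_scale`` (skipped when the raw trajectory is constant).
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n, k = int(params.n_steps), int(params.n_harmonics)
    amp = rng.uniform(*params.amplitude_range, size=(2, k))
    freq = rng.uniform(*params.frequency_range, size=(2, k))
    phase = rng.uniform(*params.phase_range, size=(2, k))
    t = np.arange(n)[:, None, None]  # (n, 1, 1)
    pos = np.sum(amp * np.sin(freq * t + phase), axis=2)  # (n, 2)

    step = np.diff(pos, axis=0)
    mean_speed = float(np.mean(np.hypot(step[:, 0], step[:, 1])))
    scale = params.speed_scale / mean_speed if mean_speed > 0 else 1.0
    pos = pos * scale
    harmonics = {
        "amplitude": amp * scale,
        "frequency": freq,
        "phase": phase,
        "scale": scale,
    }
    return Trajectory(positions=pos, harmonics=harmonics)


def differentiate(traj: Trajectory) -> VelocitySeries:
    """First differences of positions per unit timestep (length n_steps - 1)."""
    if len(traj) < 2:
        raise InputError("need at least 2 positions to differentiate")
    return VelocitySeries(velocities=np.diff(traj.positions, axis=0))


def sample_population(
    n_neurons: int,
    a0_range: tuple[float, float] = (8.0, 12.0),
    ap_range: tuple[float, float] = (8.0, 12.0),
    seed: int = 0,
) -> NeuronTuning:
    """Sample a tuned neuron population.

    Preferred directions are uniform on [-pi, pi]; baselines and modulation
    depths uniform on their ranges.  Deterministic given ``seed``.
    """
    if n_neurons < 1:
        raise ParameterError(f"n_neurons must be >= 1, got {n_neurons}")
    a0_lo, _ = _check_interval("a0_range", a0_range)
    _check_interval("ap_range", ap_range)
    if a0_lo < 0:
        raise ParameterError(f"a0_range lower bound must be >= 0, got {a0_lo}")
    rng = np.random.default_rng(seed)
    theta_p = rng.uniform(-np.pi, np.pi, size=n_neurons)
    a0 = rng.uniform(*a0_range, size=n_neurons)
    ap = rng.uniform(*ap_range, size=n_neurons)
    return NeuronTuning(theta_p=theta_p, a0=a0, ap=ap)


def tuning_mean(tuning: NeuronTuning, vel: VelocitySeries) -> np.ndarray:
    """Poisson mean matrix z (n_steps x n_neurons), clipped at zero.

    z[t, i] = max(0, a0_i + ap_i * v_t * cos(theta_t - theta_p_i)).
    """
    v = vel.speed[:, None]
    theta = vel.angle[:, None]
    z = tuning.a0[None, :] + tuning.ap[None, :] * v * np.cos(theta - tuning.theta_p[None, :])
    return np.clip(z, 0.0, None)


def simulate_spikes(tuning: NeuronTuning, vel: VelocitySeries, seed: int = 0) -> SpikeCountMatrix:
    """Independent Poisson counts with the cosine-tuning mean; seeded."""
    z = tuning_mean(tuning, vel)
    rng = np.random.default_rng(seed)
    return SpikeCountMatrix(counts=rng.poisson(z))
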