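"""Scoring, significance testing, and the three-phase fusion experiment.

Decoders are scored by root mean squared error in velocity space,

    E_rms = sqrt( (1/T) * sum_t ||v_t - vhat_t||^2 ),

with a delta-method standard error.  Experiments run three phases: (i) the
three individual decoders are trained on one shared simulated dataset,
(ii) a separate, longer trajectory provides fusion-training data (plus a
validation trajectory for ANN early stopping), and (iii) fresh test
trajectories score all five decoders, with paired one-tailed T-tests of
each fusion method against each individual decoder and a two-tailed Welch
T-test of the pooled fusion E_rms against the pooled individual E_rms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .decoders import (
    DecoderEstimate,
    decode_kalman,
    decode_linear,
    decode_pva,
    train_kalman,
    train_linear,
    train_pva,
)
from .errors import InputError, NeurofuseError, ParameterError
from .fusion import (
    ANNTopology,
    assemble_observations,
    decode_ann,
    decode_kalman_fusion,
    topology_search,
    train_ann,
    train_kalman_fusion,
)
from .rng import substream_seed
from .synthetic import (
    TrajectoryParams,
    VelocitySeries,
    differentiate,
    generate_trajectory,
    sample_population,
    simulate_spikes,
)

__all__ = [
    "DECODER_IDS",
    "INDIVIDUAL_IDS",
    "FUSION_IDS",
    "EvalResult",
    "e_rms",
    "pointwise_error",
    "TestResult",
    "paired_t_one_tailed",
    "welch_t_two_tailed",
    "ExperimentConfig",
    "TrialResult",
    "ExperimentResult",
    "run_experiment",
]

INDIVIDUAL_IDS = ("kalman", "pva", "linear")
FUSION_IDS = ("kalman_fusion", "ann_fusion")
DECODER_IDS = INDIVIDUAL_IDS + FUSION_IDS


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class EvalResult:
    decoder_id: str
    e_rms: float
    std_err: float


def _velocity_array(x) -> np.ndarray:
    if isinstance(x, VelocitySeries):
        return x.velocities
    if isinstance(x, DecoderEstimate):
        return x.velocities
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InputError(f"expected an (n, 2) velocity array, got shape {arr.shape}")
    return arr


def e_rms(truth, est) -> EvalResult:
    """Root mean squared error in velocity space, with delta-method s.e.

    se(E_rms) = sd(per-step squared errors) / (2 * E_rms * sqrt(T));
    zero when the estimate is exact.
    """
    V = _velocity_array(truth)
    Vh = _velocity_array(est)
    if V.shape != Vh.shape:
        raise InputError(f"length mismatch: truth {V.shape} vs estimate {Vh.shape}")
    sq = np.sum((V - Vh) ** 2, axis=1)
    mse = float(np.mean(sq))
    rms = float(np.sqrt(mse))
    if rms == 0.0 or sq.size < 2:
        se = 0.0
    else:
        se = float(np.std(sq, ddof=1) / (2.0 * rms * np.sqrt(sq.size)))
    decoder_id = est.decoder_id if isinstance(est, DecoderEstimate) else "estimate"
    return EvalResult(decoder_id=decoder_id, e_rms=rms, std_err=se)


def pointwise_error(truth, est, smoothing_window: int = 1) -> np.ndarray:
    """Per-timestep Euclidean error, optionally smoothed by a centered moving average."""
    if smoothing_window < 1:
        raise ParameterError(f"smoothing_window must be >= 1, got {smoothing_window}")
    V = _velocity_array(truth)
    Vh = _velocity_array(est)
    if V.shape != Vh.shape:
        raise InputError(f"length mismatch: truth {V.shape} vs estimate {Vh.shape}")
    err = np.sqrt(np.sum((V - Vh) ** 2, axis=1))
    if smoothing_window == 1:
        return err
    kernel = np.ones(smoothing_window) / smoothing_window
    return np.convolve(err, kernel, mode="same")


# ---------------------------------------------------------------------------
# significance tests


@dataclass(frozen=True)
class TestResult:
    """T-test outcome; ``degenerate`` marks zero-variance inputs where the
    statistic is not defined and the p-value is a documented boundary value."""

    statistic: float
    dof: float
    p_value: float
    degenerate: bool = False


def paired_t_one_tailed(errors_a, errors_b) -> TestResult:
    """Paired one-tailed T-test of mean(a) < mean(b) on per-trial errors.

    The statistic is t = mean(d) / (sd(d) / sqrt(n)) with d = b - a and
    n - 1 degrees of freedom; p is the upper-tail probability.  Zero-variance
    differences return a degenerate result: p = 0.5 when the mean difference
    is also zero, else 0 or 1 with an infinite statistic.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired samples must be 1-D arrays of equal length")
    n = a.size
    if n < 2:
        raise InputError("need at least 2 pairs")
    d = b - a
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return TestResult(statistic=0.0, dof=n - 1, p_value=0.5, degenerate=True)
        stat = np.inf if mean > 0 else -np.inf
        return TestResult(statistic=stat, dof=n - 1, p_value=0.0 if mean > 0 else 1.0,
                          degenerate=True)
    t = mean / (sd / np.sqrt(n))
    return TestResult(statistic=float(t), dof=n - 1,
                      p_value=float(scipy.stats.t.sf(t, n - 1)))


def welch_t_two_tailed(group_a, group_b) -> TestResult:
    """Two-tailed Welch T-test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 one-dimensional samples")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = a.size, b.size
    denom_sq = va / na + vb / nb
    diff = float(np.mean(a) - np.mean(b))
    if denom_sq == 0.0:
        if diff == 0.0:
            return TestResult(statistic=0.0, dof=na + nb - 2, p_value=1.0, degenerate=True)
        return TestResult(statistic=np.inf if diff > 0 else -np.inf,
                          dof=na + nb - 2, p_value=0.0, degenerate=True)
    t = diff / np.sqrt(denom_sq)
    dof = denom_sq ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return TestResult(statistic=float(t), dof=float(dof),
                      p_value=float(2.0 * scipy.stats.t.sf(abs(t), dof)))


# ---------------------------------------------------------------------------
# experiment orchestration


@dataclass(frozen=True)
class ExperimentConfig:
    """Three-phase experiment layout and all module parameters.

    Defaults follow the evaluated protocol: 50 neurons, 3,000 training
    timesteps (1,500 in the poor-quality regime), 10,000 fusion-training
    timesteps, 3,000 validation and test timesteps.
    """

    n_neurons: int = 50
    training_steps: int = 3000
    fusion_training_steps: int = 10000
    validation_steps: int = 3000
    test_steps: int = 3000
    n_test_trials: int = 4
    ann_mode: str = "fixed"  # "fixed" or "grid_search"
    fixed_topology: tuple[int, int] = (6, 0)
    a0_range: tuple[float, float] = (8.0, 12.0)
    ap_range: tuple[float, float] = (8.0, 12.0)
    n_harmonics: int = 64
    amplitude_range: tuple[float, float] = (0.5, 2.0)
    frequency_range: tuple[float, float] = (0.01, 0.8)
    phase_range: tuple[float, float] = (0.0, 2.0 * np.pi)
    speed_scale: float = 1.0
    linear_window: int = 4
    kalman_center: bool = True
    ann_max_epochs: int = 500
    ann_patience: int = 15
    keep_pointwise: bool = False
    pointwise_smoothing: int = 1
    base_seed: int = 0

    def __post_init__(self):
        for name in ("n_neurons", "training_steps", "fusion_training_steps",
                     "validation_steps", "test_steps", "n_test_trials"):
            if int(getattr(self, name)) < 1:
                raise ParameterError(f"{name} must be >= 1")
        for name in ("training_steps", "fusion_training_steps", "validation_steps",
                     "test_steps"):
            if int(getattr(self, name)) < self.linear_window:
                raise ParameterError(f"{name} must be >= linear window length")
        if self.ann_mode not in ("fixed", "grid_search"):
            raise ParameterError(f"ann_mode must be 'fixed' or 'grid_search', got {self.ann_mode!r}")

    @classmethod
    def high_quality(cls, **overrides) -> "ExperimentConfig":
        """High-quality regime: 3,000-step individual-decoder training."""
        return cls(**{"training_steps": 3000, **overrides})

    @classmethod
    def poor_quality(cls, **overrides) -> "ExperimentConfig":
        """Poor-quality regime: 1,500-step individual-decoder training."""
        return cls(**{"training_steps": 1500, **overrides})

    def trajectory_params(self, n_velocity_steps: int, seed: int) -> TrajectoryParams:
        # one extra position so first differences give n_velocity_steps velocities
        return TrajectoryParams(
            n_steps=n_velocity_steps + 1,
            n_harmonics=self.n_harmonics,
            amplitude_range=self.amplitude_range,
            frequency_range=self.frequency_range,
            phase_range=self.phase_range,
            speed_scale=self.speed_scale,
            seed=seed,
        )


@dataclass
class TrialResult:
    index: int
    evals: dict[str, EvalResult]
    pointwise: dict[str, np.ndarray] | None = None


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    trials: list[TrialResult]
    failures: list[dict]
    stats: dict
    models: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def e_rms_table(self) -> tuple[tuple[str, ...], np.ndarray]:
        """(decoder ids, trials x decoders matrix of E_rms values)."""
        table = np.array([[t.evals[d].e_rms for d in DECODER_IDS] for t in self.trials])
        return DECODER_IDS, table

    def per_decoder_errors(self) -> dict[str, np.ndarray]:
        ids, table = self.e_rms_table()
        return {d: table[:, i] for i, d in enumerate(ids)}


def _simulate_dataset(config: ExperimentConfig, tuning, traj_stream: str,
                      spike_stream: str, n_steps: int, index: int = 0):
    seed = config.base_seed
    params = config.trajectory_params(n_steps, substream_seed(seed, traj_stream, index))
    traj = generate_trajectory(params)
    vel = differentiate(traj)
    spikes = simulate_spikes(tuning, vel, substream_seed(seed, spike_stream, index))
    return traj, vel, spikes


def _decode_individuals(models: dict, spikes) -> list[DecoderEstimate]:
    return [
        decode_kalman(models["kalman"], spikes),
        decode_pva(models["pva"], spikes),
        decode_linear(models["linear"], spikes),
    ]


def run_experiment(config: ExperimentConfig, progress: bool = False) -> ExperimentResult:
    """Run the full three-phase protocol; deterministic given the config.

    Per-trial decoding failures are recorded with provenance and the
    experiment continues; significance tests use the completed trials.
    """
    seed = config.base_seed
    models: dict = {}

    # phase 1: individual decoder training on one shared dataset
    tuning = sample_population(config.n_neurons, config.a0_range, config.ap_range,
                               seed=substream_seed(seed, "tuning"))
    traj, vel, spikes = _simulate_dataset(config, tuning, "trajectory-train",
                                          "spikes-train", config.training_steps)
    models["kalman"] = train_kalman(spikes, vel, center=config.kalman_center)
    models["pva"] = train_pva(spikes, vel)
    models["linear"] = train_linear(spikes, vel, L=config.linear_window)
    models["tuning"] = tuning

    # phase 2: fusion decoder training on a separate trajectory
    _, fus_vel, fus_spikes = _simulate_dataset(config, tuning, "trajectory-fusion",
                                               "spikes-fusion", config.fusion_training_steps)
    fus_obs = assemble_observations(_decode_individuals(models, fus_spikes))
    models["kalman_fusion"] = train_kalman_fusion(fus_obs, fus_vel,
                                                  center=config.kalman_center)

    _, val_vel, val_spikes = _simulate_dataset(config, tuning, "trajectory-validation",
                                               "spikes-validation", config.validation_steps)
    val_obs = assemble_observations(_decode_individuals(models, val_spikes))
    ann_seed = substream_seed(seed, "ann-init")
    if config.ann_mode == "grid_search":
        search = topology_search(fus_obs, fus_vel, val_obs, val_vel, val_obs, val_vel,
                                 seed=ann_seed, max_epochs=config.ann_max_epochs,
                                 patience=config.ann_patience)
        models["ann_fusion"] = search.best_model
        models["topology_search"] = search
    else:
        topo = ANNTopology(*config.fixed_topology)
        models["ann_fusion"] = train_ann(fus_obs, fus_vel, val_obs, val_vel, topo,
                                         seed=ann_seed, max_epochs=config.ann_max_epochs,
                                         patience=config.ann_patience)

    # phase 3: fresh test trajectories for all five decoders
    trials: list[TrialResult] = []
    failures: list[dict] = []
    for trial in range(config.n_test_trials):
        try:
            _, t_vel, t_spikes = _simulate_dataset(config, tuning, "trajectory-test",
                                                   "spikes-test", config.test_steps,
                                                   index=trial)
            estimates = _decode_individuals(models, t_spikes)
            obs = assemble_observations(estimates)
            estimates.append(decode_kalman_fusion(models["kalman_fusion"], obs))
            estimates.append(decode_ann(models["ann_fusion"], obs))
            evals = {est.decoder_id: e_rms(t_vel, est) for est in estimates}
            pw = None
            if config.keep_pointwise:
                pw = {est.decoder_id: pointwise_error(t_vel, est, config.pointwise_smoothing)
                      for est in estimates}
            trials.append(TrialResult(index=trial, evals=evals, pointwise=pw))
        except NeurofuseError as exc:
            failures.append({"trial": trial, "error": str(exc),
                             "seed": substream_seed(seed, "spikes-test", trial)})
        if progress:
            print(f"trial {trial + 1}/{config.n_test_trials} done")

    result = ExperimentResult(config=config, trials=trials, failures=failures,
                              stats={}, models=models,
                              seeds={"base_seed": seed})
    result.stats = _experiment_stats(result)
    return result


def _experiment_stats(result: ExperimentResult) -> dict:
    if len(result.trials) < 2:
        return {}
    errors = result.per_decoder_errors()
    stats: dict = {"n_trials": len(result.trials), "mean_e_rms": {
        d: float(np.mean(v)) for d, v in errors.items()}}
    paired = {}
    for fusion in FUSION_IDS:
        for individual in INDIVIDUAL_IDS:
            paired[f"{fusion}_vs_{individual}"] = paired_t_one_tailed(
                errors[fusion], errors[individual])
    stats["paired_one_tailed"] = paired
    pooled_fusion = np.concatenate([errors[d] for d in FUSION_IDS])
    pooled_individual = np.concatenate([errors[d] for d in INDIVIDUAL_IDS])
    stats["welch_fusion_vs_individual"] = welch_t_two_tailed(pooled_fusion, pooled_individual)
    return stats
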