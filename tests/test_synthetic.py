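"""Unit and property tests for trajectory and spike simulation."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import neurofuse as nf
from neurofuse.errors import InputError, ParameterError


class TestTrajectoryParams:
    def test_invalid_interval_rejected(self):
        with pytest.raises(ParameterError):
            nf.TrajectoryParams(amplitude_range=(2.0, 0.5))

    def test_n_steps_too_small(self):
        with pytest.raises(ParameterError):
            nf.TrajectoryParams(n_steps=1)

    def test_nonpositive_speed_scale(self):
        with pytest.raises(ParameterError):
            nf.TrajectoryParams(speed_scale=0.0)


class TestGenerateTrajectory:
    def test_seeded_determinism_single_harmonic(self):
        params = nf.TrajectoryParams(n_steps=100, n_harmonics=1,
                                     amplitude_range=(1.0, 1.0),
                                     phase_range=(0.0, 0.0), seed=3)
        a = nf.generate_trajectory(params)
        b = nf.generate_trajectory(params)
        np.testing.assert_array_equal(a.positions, b.positions)
        # single sinusoid with zero phase starts at the origin
        np.testing.assert_allclose(a.positions[0], [0.0, 0.0], atol=1e-12)

    def test_zero_frequency_gives_constant_positions(self):
        params = nf.TrajectoryParams(n_steps=50, frequency_range=(0.0, 0.0), seed=1)
        traj = nf.generate_trajectory(params)
        np.testing.assert_allclose(traj.positions - traj.positions[0], 0.0, atol=1e-12)
        vel = nf.differentiate(traj)
        np.testing.assert_allclose(vel.velocities, 0.0, atol=1e-12)

    def test_mean_speed_matches_target(self):
        # oracle: recompute mean ||delta position|| directly from the output
        params = nf.TrajectoryParams(n_steps=3000, speed_scale=1.0, seed=5)
        traj = nf.generate_trajectory(params)
        steps = np.diff(traj.positions, axis=0)
        mean_speed = np.mean(np.hypot(steps[:, 0], steps[:, 1]))
        assert abs(mean_speed - 1.0) < 0.02

    def test_different_seeds_differ(self):
        p1 = nf.TrajectoryParams(n_steps=100, seed=1)
        p2 = nf.TrajectoryParams(n_steps=100, seed=2)
        assert not np.allclose(nf.generate_trajectory(p1).positions,
                               nf.generate_trajectory(p2).positions)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), n_steps=st.integers(10, 300))
    def test_smoothness_bound(self, seed, n_steps):
        # second difference of A*sin(w t + phi) is bounded by A*w^2 per
        # harmonic; sum over harmonics and coordinates gives a hard bound
        params = nf.TrajectoryParams(n_steps=n_steps, seed=seed)
        traj = nf.generate_trajectory(params)
        amp, freq = traj.harmonics["amplitude"], traj.harmonics["frequency"]
        bound = np.sqrt(2.0) * np.max(np.sum(amp * freq ** 2, axis=1))
        dv = np.diff(nf.differentiate(traj).velocities, axis=0)
        max_change = np.max(np.hypot(dv[:, 0], dv[:, 1])) if len(dv) else 0.0
        assert max_change <= bound + 1e-9


class TestDifferentiate:
    def test_constant_slope(self):
        traj = nf.Trajectory(positions=np.array([[0, 0], [1, 0], [2, 0]], dtype=float))
        vel = nf.differentiate(traj)
        np.testing.assert_allclose(vel.velocities, [[1, 0], [1, 0]])

    def test_constant_positions(self):
        traj = nf.Trajectory(positions=np.ones((5, 2)))
        np.testing.assert_allclose(nf.differentiate(traj).velocities, 0.0)

    def test_cumsum_inverse_identity(self):
        traj = nf.generate_trajectory(nf.TrajectoryParams(n_steps=200, seed=9))
        vel = nf.differentiate(traj)
        rebuilt = traj.positions[0] + np.vstack(
            [np.zeros(2), np.cumsum(vel.velocities, axis=0)])
        np.testing.assert_allclose(rebuilt, traj.positions, atol=1e-9)

    def test_too_short(self):
        with pytest.raises(InputError):
            nf.Trajectory(positions=np.zeros((1, 2)))


class TestSamplePopulation:
    def test_default_population_size(self):
        tuning = nf.sample_population(50, seed=0)
        assert tuning.n_neurons == 50
        assert np.all(np.abs(tuning.theta_p) <= np.pi)
        assert np.all(tuning.a0 >= 0)

    def test_point_intervals(self):
        tuning = nf.sample_population(5, a0_range=(3.0, 3.0), ap_range=(7.0, 7.0), seed=1)
        np.testing.assert_allclose(tuning.a0, 3.0)
        np.testing.assert_allclose(tuning.ap, 7.0)

    def test_preferred_direction_uniformity(self):
        # oracle: Kolmogorov-Smirnov against the uniform CDF on [-pi, pi]
        tuning = nf.sample_population(10_000, seed=2)
        stat = scipy.stats.kstest(tuning.theta_p,
                                  scipy.stats.uniform(loc=-np.pi, scale=2 * np.pi).cdf)
        assert stat.pvalue > 0.01

    def test_negative_a0_bound_rejected(self):
        with pytest.raises(ParameterError):
            nf.sample_population(5, a0_range=(-1.0, 2.0))

    def test_determinism(self):
        a = nf.sample_population(10, seed=4)
        b = nf.sample_population(10, seed=4)
        np.testing.assert_array_equal(a.theta_p, b.theta_p)


class TestTuningMean:
    def test_unmodulated_neuron(self):
        tuning = nf.NeuronTuning(theta_p=np.array([0.3]), a0=np.array([5.0]),
                                 ap=np.array([0.0]))
        vel = nf.VelocitySeries(velocities=np.array([[1.0, 2.0], [-3.0, 0.5]]))
        np.testing.assert_allclose(nf.tuning_mean(tuning, vel), 5.0)

    def test_movement_along_preferred_direction(self):
        tuning = nf.NeuronTuning(theta_p=np.array([0.0]), a0=np.array([2.0]),
                                 ap=np.array([3.0]))
        vel = nf.VelocitySeries(velocities=np.array([[1.5, 0.0]]))
        np.testing.assert_allclose(nf.tuning_mean(tuning, vel), [[2.0 + 3.0 * 1.5]])

    def test_antiparallel_clips_to_zero(self):
        # hand oracle: a0 + ap*v*cos(pi) = 2 - 3*1.5 = -2.5 -> clipped to 0
        tuning = nf.NeuronTuning(theta_p=np.array([0.0]), a0=np.array([2.0]),
                                 ap=np.array([3.0]))
        vel = nf.VelocitySeries(velocities=np.array([[-1.5, 0.0]]))
        np.testing.assert_allclose(nf.tuning_mean(tuning, vel), [[0.0]])

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_reflection_symmetry(self, seed):
        # reflecting preferred directions and velocities through the origin
        # leaves the means unchanged
        rng = np.random.default_rng(seed)
        tuning = nf.sample_population(8, seed=seed)
        vel = nf.VelocitySeries(velocities=rng.normal(size=(20, 2)))
        theta_ref = np.arctan2(np.sin(tuning.theta_p + np.pi),
                               np.cos(tuning.theta_p + np.pi))
        reflected = nf.NeuronTuning(theta_p=theta_ref, a0=tuning.a0, ap=tuning.ap)
        vel_ref = nf.VelocitySeries(velocities=-vel.velocities)
        np.testing.assert_allclose(nf.tuning_mean(tuning, vel),
                                   nf.tuning_mean(reflected, vel_ref), atol=1e-9)


class TestSimulateSpikes:
    def test_zero_mean_gives_zero_counts(self):
        tuning = nf.NeuronTuning(theta_p=np.array([0.0]), a0=np.array([0.0]),
                                 ap=np.array([0.0]))
        vel = nf.VelocitySeries(velocities=np.zeros((100, 2)))
        assert nf.simulate_spikes(tuning, vel, seed=0).counts.sum() == 0

    @pytest.mark.parametrize("lam", [0.5, 2.0, 10.0])
    def test_poisson_moments(self, lam):
        # oracle: Poisson mean and variance both equal lambda
        n = 100_000
        tuning = nf.NeuronTuning(theta_p=np.array([0.0]), a0=np.array([lam]),
                                 ap=np.array([0.0]))
        vel = nf.VelocitySeries(velocities=np.zeros((n, 2)))
        counts = nf.simulate_spikes(tuning, vel, seed=int(lam * 10)).counts[:, 0]
        assert abs(counts.mean() - lam) < 3.0 * np.sqrt(lam / n)
        assert abs(counts.var() - lam) < 0.05 * lam

    def test_seeded_determinism(self, small_dataset):
        tuning, vel, _ = small_dataset
        a = nf.simulate_spikes(tuning, vel, seed=99)
        b = nf.simulate_spikes(tuning, vel, seed=99)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_shape_and_nonnegativity(self, small_dataset):
        tuning, vel, spikes = small_dataset
        assert spikes.counts.shape == (len(vel), tuning.n_neurons)
        assert np.all(spikes.counts >= 0)


class TestSeedSubstreams:
    def test_named_streams_differ(self):
        s1 = nf.substream_seed(0, "trajectory")
        s2 = nf.substream_seed(0, "tuning")
        assert s1 != s2

    def test_indexed_streams_differ(self):
        assert nf.substream_seed(0, "spikes-test", 0) != nf.substream_seed(0, "spikes-test", 1)

    def test_unknown_stream_rejected(self):
        with pytest.raises(ParameterError):
            nf.substream_seed(0, "nonsense")
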