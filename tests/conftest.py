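"""Shared fixtures: small simulated datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import neurofuse as nf


@pytest.fixture(scope="session")
def small_population() -> nf.NeuronTuning:
    return nf.sample_population(50, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_population):
    """500-step simulated trial: (tuning, velocities, spikes)."""
    params = nf.TrajectoryParams(n_steps=501, seed=21)
    vel = nf.differentiate(nf.generate_trajectory(params))
    spikes = nf.simulate_spikes(small_population, vel, seed=31)
    return small_population, vel, spikes


@pytest.fixture(scope="session")
def noisy_pseudo_decoders():
    """Truth plus three unbiased Gaussian-noise pseudo-decoders.

    Truth is iid Gaussian with a large standard deviation so the optimal
    fusion of the three streams is essentially the static precision-weighted
    combination.
    """
    rng = np.random.default_rng(7)
    n = 6000
    sigmas = (0.3, 0.5, 0.8)
    truth = rng.normal(0.0, 5.0, size=(n, 2))
    estimates = [
        nf.DecoderEstimate(decoder_id=name,
                           velocities=truth + rng.normal(0.0, s, size=(n, 2)))
        for name, s in zip(("kalman", "pva", "linear"), sigmas)
    ]
    return truth, estimates, sigmas
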