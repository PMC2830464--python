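"""ANN fusion tests: forward pass, SCG training, early stopping, topology search."""

import numpy as np
import pytest

import neurofuse as nf
from neurofuse.errors import ParameterError
from neurofuse.fusion.ann import ANNModel
from neurofuse.fusion.scg import scg_minimize
from neurofuse.fusion.search import cell_seed


def _identity_model(topology, n_inputs=6):
    sizes = (n_inputs, *topology.layer_sizes, 2)
    weights = [np.zeros((a, b)) for a, b in zip(sizes[:-1], sizes[1:])]
    biases = [np.zeros(b) for b in sizes[1:]]
    return ANNModel(topology=topology, weights=weights, biases=biases,
                    input_mean=np.zeros(n_inputs), input_sd=np.ones(n_inputs))


def _linear_fusion_data(n=2000, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 6))
    B = rng.normal(size=(6, 2))
    Y = X @ B + 0.5
    return X, Y


class TestTopology:
    def test_invalid_sizes(self):
        with pytest.raises(ParameterError):
            nf.ANNTopology(h1=0)
        with pytest.raises(ParameterError):
            nf.ANNTopology(h1=1, h2=-1)

    def test_layer_sizes(self):
        assert nf.ANNTopology(3, 0).layer_sizes == (3,)
        assert nf.ANNTopology(3, 5).layer_sizes == (3, 5)


class TestForwardPass:
    def test_zero_network_outputs_zero(self):
        model = _identity_model(nf.ANNTopology(4, 3))
        out = nf.ann_forward(model, np.ones(6))
        np.testing.assert_allclose(out, 0.0)

    def test_tansigmoid_range_strict(self):
        model = _identity_model(nf.ANNTopology(1, 0))
        model.weights[0][:] = 3.0  # strongly saturating input
        model.weights[1][:] = 1.0
        hidden = np.tanh(np.ones(6) @ model.weights[0] + model.biases[0])
        assert np.all(np.abs(hidden) < 1.0)

    def test_hand_forward_pass(self):
        # oracle: manual computation of w2*tanh(w1.x + b1) + b2
        model = _identity_model(nf.ANNTopology(1, 0), n_inputs=2)
        model.weights[0][:, 0] = [0.5, -0.25]
        model.biases[0][:] = 0.1
        model.weights[1][0, :] = [2.0, -3.0]
        model.biases[1][:] = [0.05, -0.05]
        x = np.array([1.0, 2.0])
        h = np.tanh(0.5 * 1.0 - 0.25 * 2.0 + 0.1)
        expected = np.array([2.0 * h + 0.05, -3.0 * h - 0.05])
        np.testing.assert_allclose(nf.ann_forward(model, x), expected, atol=1e-12)

    def test_matrix_input(self):
        model = _identity_model(nf.ANNTopology(2, 0))
        out = nf.ann_forward(model, np.ones((7, 6)))
        assert out.shape == (7, 2)


class TestSCG:
    def test_quadratic_minimization(self):
        # convex quadratic: SCG must find the known minimum
        A = np.diag([1.0, 4.0, 9.0])
        b = np.array([1.0, -2.0, 3.0])

        def f_and_g(w):
            return 0.5 * w @ A @ w - b @ w, A @ w - b

        w, f, _ = scg_minimize(f_and_g, np.zeros(3), max_iter=200)
        np.testing.assert_allclose(w, np.linalg.solve(A, b), atol=1e-6)

    def test_rosenbrock_descent(self):
        def f_and_g(w):
            x, y = w
            f = (1 - x) ** 2 + 100 * (y - x * x) ** 2
            g = np.array([-2 * (1 - x) - 400 * x * (y - x * x), 200 * (y - x * x)])
            return f, g

        w, f, _ = scg_minimize(f_and_g, np.array([-1.0, 1.0]), max_iter=2000)
        assert f < 1e-4


class TestTrainANN:
    def test_linear_target_matches_ols(self):
        # oracle: OLS fit of the same data; the (1,0) network approximates
        # the linear map on in-range inputs
        X, Y = _linear_fusion_data()
        # single-output-direction target so one hidden unit suffices
        w = np.array([[0.3], [-0.2], [0.1], [0.05], [-0.1], [0.2]])
        Y = X @ np.hstack([w, -w]) * 0.1  # small scale keeps tanh near-linear
        model = nf.train_ann(X[:1500], Y[:1500], X[1500:], Y[1500:],
                             nf.ANNTopology(1, 0), seed=0, max_epochs=300)
        pred = nf.ann_forward(model, X[1500:])
        coef, *_ = np.linalg.lstsq(np.hstack([X[:1500], np.ones((1500, 1))]),
                                   Y[:1500], rcond=None)
        ols_pred = np.hstack([X[1500:], np.ones((500, 1))]) @ coef
        mse_ann = np.mean((pred - Y[1500:]) ** 2)
        mse_ols = np.mean((ols_pred - Y[1500:]) ** 2)
        assert mse_ann < max(10 * mse_ols, 1e-6)

    def test_seeded_determinism(self):
        X, Y = _linear_fusion_data(800, seed=1)
        kwargs = dict(topology=nf.ANNTopology(4, 0), seed=42, max_epochs=50)
        m1 = nf.train_ann(X[:600], Y[:600], X[600:], Y[600:], **kwargs)
        m2 = nf.train_ann(X[:600], Y[:600], X[600:], Y[600:], **kwargs)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_pure_noise_early_stopping(self):
        # oracle: best validation MSE near the target variance; stops early
        rng = np.random.default_rng(2)
        X = rng.normal(size=(1200, 6))
        Y = rng.normal(size=(1200, 2))
        model = nf.train_ann(X[:900], Y[:900], X[900:], Y[900:],
                             nf.ANNTopology(6, 0), seed=3, max_epochs=500, patience=10)
        assert len(model.val_curve) < 500
        best = model.val_curve.min() if len(model.val_curve) else np.inf
        assert best == pytest.approx(np.mean(Y[900:] ** 2), rel=0.25)

    def test_early_stopping_returns_best_epoch_weights(self):
        X, Y = _linear_fusion_data(1000, seed=4)
        Y = Y + np.random.default_rng(5).normal(0, 0.5, Y.shape)
        model = nf.train_ann(X[:700], Y[:700], X[700:], Y[700:],
                             nf.ANNTopology(5, 2), seed=6, max_epochs=120)
        val_mse = np.mean((nf.ann_forward(model, X[700:]) - Y[700:]) ** 2)
        assert val_mse <= model.val_curve.min() + 1e-9


@pytest.fixture(scope="module")
def tiny_fusion_data():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(400, 6))
    Y = X[:, :2] * 0.5 + rng.normal(0, 0.2, size=(400, 2))
    return (X[:200], Y[:200], X[200:300], Y[200:300], X[300:], Y[300:])


class TestTopologySearch:
    def test_singleton_grid(self, tiny_fusion_data):
        result = nf.topology_search(*tiny_fusion_data, seed=0,
                                    h1_grid=[1], h2_grid=[0], max_epochs=20)
        assert result.e_rms_matrix.shape == (1, 1)
        assert result.n_trained == 1
        assert result.best_topology == nf.ANNTopology(1, 0)

    def test_cell_seed_order_invariance(self, tiny_fusion_data):
        # per-cell seeds derive from (seed, h1, h2): the value of one cell is
        # independent of which other cells are in the grid
        full = nf.topology_search(*tiny_fusion_data, seed=1,
                                  h1_grid=[1, 2], h2_grid=[0, 1], max_epochs=15)
        solo = nf.topology_search(*tiny_fusion_data, seed=1,
                                  h1_grid=[2], h2_grid=[1], max_epochs=15)
        assert full.e_rms_matrix[1, 1] == pytest.approx(solo.e_rms_matrix[0, 0], abs=0)

    def test_single_layer_competitive(self, small_dataset):
        # realistic trial: best single-hidden-layer E_rms is at most the
        # median of the full (reduced) matrix, recomputed from the emitted
        # matrix itself
        tuning, vel, spikes = small_dataset
        kal = nf.train_kalman(spikes, vel)
        pva = nf.train_pva(spikes, vel)
        lin = nf.train_linear(spikes, vel)
        ests = [nf.decode_kalman(kal, spikes), nf.decode_pva(pva, spikes),
                nf.decode_linear(lin, spikes)]
        obs = nf.assemble_observations(ests)
        n = len(vel)
        tr, va = slice(0, n // 2), slice(n // 2, 3 * n // 4)
        te = slice(3 * n // 4, n)
        import numpy as _np
        O, V = obs.observations, vel.velocities
        result = nf.topology_search(O[tr], V[tr], O[va], V[va], O[te], V[te],
                                    seed=2, h1_grid=range(1, 7), h2_grid=range(0, 4),
                                    max_epochs=40)
        matrix = result.e_rms_matrix
        assert _np.nanmin(matrix[:, 0]) <= _np.nanmedian(matrix)

    def test_best_is_matrix_minimum(self, tiny_fusion_data):
        result = nf.topology_search(*tiny_fusion_data, seed=3,
                                    h1_grid=[1, 2, 3], h2_grid=[0, 1], max_epochs=15)
        i = result.h1_grid.index(result.best_topology.h1)
        j = result.h2_grid.index(result.best_topology.h2)
        assert result.e_rms_matrix[i, j] == np.nanmin(result.e_rms_matrix)
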