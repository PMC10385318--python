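import itertools

import numpy as np
import pytest

from epifed.graph import (
    ChannelGraph,
    GCNNParams,
    batch_node_features,
    build_graph,
    gcnn_forward,
    init_params,
    load_params,
    predict_proba,
    renormalize_adjacency,
    save_params,
    train_local,
)
from epifed.types import RunConfig


def brute_force_renormalize(a):
    a_tilde = a + np.eye(len(a))
    d = np.diag(a_tilde.sum(axis=1))
    d_inv_sqrt = np.linalg.inv(np.sqrt(d))
    return d_inv_sqrt @ a_tilde @ d_inv_sqrt


class TestRenormalization:
    def test_two_identical_channels(self):
        t = np.linspace(0, 1, 200)
        x = np.stack([np.sin(7 * t), np.sin(7 * t)], axis=1)
        g = build_graph(x, corr_threshold=0.3)
        np.testing.assert_allclose(g.adjacency, [[0, 1], [1, 0]], atol=1e-12)
        np.testing.assert_allclose(g.a_hat, [[0.5, 0.5], [0.5, 0.5]], atol=1e-12)

    def test_independent_channels_identity(self):
        g0 = np.random.default_rng(0)
        x = g0.standard_normal((4000, 3))
        g = build_graph(x, corr_threshold=0.9)
        np.testing.assert_array_equal(g.adjacency, np.zeros((3, 3)))
        np.testing.assert_allclose(g.a_hat, np.eye(3))

    def test_constant_channel_correlates_zero(self):
        g0 = np.random.default_rng(1)
        x = g0.standard_normal((500, 3))
        x[:, 2] = 4.2
        g = build_graph(x, corr_threshold=0.0)
        assert np.all(g.adjacency[2] == 0) and np.all(g.adjacency[:, 2] == 0)

    def test_exhaustive_small_graphs(self):
        """All 0/1 adjacencies on 2..5 nodes match the brute-force operator
        (the full 6-node sweep runs in the acceptance suite)."""
        for n in range(2, 6):
            pairs = list(itertools.combinations(range(n), 2))
            for bits in range(2 ** len(pairs)):
                a = np.zeros((n, n))
                for b, (i, j) in enumerate(pairs):
                    if (bits >> b) & 1:
                        a[i, j] = a[j, i] = 1.0
                np.testing.assert_allclose(
                    renormalize_adjacency(a), brute_force_renormalize(a), atol=1e-12
                )

    def test_eigenvalues_in_unit_interval(self):
        g0 = np.random.default_rng(2)
        for _ in range(50):
            n = int(g0.integers(2, 9))
            a = (g0.random((n, n)) < 0.4).astype(float) * g0.random((n, n))
            a = np.triu(a, 1)
            a = a + a.T
            a_hat = renormalize_adjacency(a)
            np.testing.assert_allclose(a_hat, a_hat.T, atol=1e-12)
            ev = np.linalg.eigvalsh(a_hat)
            assert ev.min() >= -1 - 1e-9 and ev.max() <= 1 + 1e-9

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            renormalize_adjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))


def _random_inputs(rng, m=5, b=4):
    Xa = rng.standard_normal((b, m, 4))
    Xb = rng.standard_normal((b, m, 4))
    ga = rng.random((b, m))
    gb = rng.random((b, m))
    a = (rng.random((m, m)) < 0.5).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    graph = ChannelGraph(adjacency=a, a_hat=renormalize_adjacency(a))
    return graph, Xa, ga, Xb, gb


class TestForward:
    def test_softmax_sums_to_one(self):
        rng = np.random.default_rng(3)
        params = init_params(seed=0)
        for _ in range(100):
            graph, Xa, ga, Xb, gb = _random_inputs(rng)
            p, _ = gcnn_forward(params, graph, Xa, ga, Xb, gb)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_gate_annihilates_content(self):
        rng = np.random.default_rng(4)
        params = init_params(seed=0)
        graph, Xa, ga, Xb, gb = _random_inputs(rng)
        z = np.zeros_like(ga)
        p1, _ = gcnn_forward(params, graph, Xa, z, Xb, z)
        p2, _ = gcnn_forward(params, graph, Xa * 5 + 1, z, Xb - 7, z)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_single_node_linear_identity_trace(self):
        """1-node graph, identity conv weights, linear activations: the head
        sees exactly the (gated) input features."""
        params = init_params(hidden_units=(4, 4), dropout=0.0, seed=0,
                             activations=("linear", "linear", "linear"))
        for b in (0, 1):
            params.weights[f"W1_{b}"] = np.eye(4)
            params.weights[f"W2_{b}"] = np.eye(4)
        params.weights["Wd"] = np.vstack([np.eye(2), np.zeros((6, 2))])
        params.weights["bd"] = np.zeros(2)
        graph = ChannelGraph(adjacency=np.zeros((1, 1)),
                             a_hat=renormalize_adjacency(np.zeros((1, 1))))
        X = np.array([[[0.3, -0.2, 0.5, 1.0]]])
        ones = np.ones((1, 1))
        p, cache = gcnn_forward(params, graph, X, ones, X, ones)
        u = cache["u"]
        np.testing.assert_allclose(u, X[0, 0, :2][None, :], atol=1e-12)

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        params = init_params(seed=1)
        graph, Xa, ga, Xb, gb = _random_inputs(rng, m=6)
        perm = rng.permutation(6)
        graph_p = ChannelGraph(
            adjacency=graph.adjacency[np.ix_(perm, perm)],
            a_hat=graph.a_hat[np.ix_(perm, perm)],
        )
        p1, _ = gcnn_forward(params, graph, Xa, ga, Xb, gb)
        p2, _ = gcnn_forward(
            params, graph_p, Xa[:, perm], ga[:, perm], Xb[:, perm], gb[:, perm]
        )
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_dimension_mismatch_raises(self):
        rng = np.random.default_rng(6)
        params = init_params(seed=0)
        graph, Xa, ga, Xb, gb = _random_inputs(rng)
        with pytest.raises(ValueError):
            gcnn_forward(params, graph, Xa[:, :, :2], ga, Xb, gb)


class TestGradients:
    def test_finite_difference_check(self):
        """Backprop gradients match central differences on a tiny model."""
        from epifed.graph import gcnn_backward

        rng = np.random.default_rng(7)
        params = init_params(hidden_units=(3, 3), dropout=0.0, seed=2)
        graph, Xa, ga, Xb, gb = _random_inputs(rng, m=3, b=5)
        y = np.array([0, 1, 1, 0, 1])

        def loss_at(p):
            probs, _ = gcnn_forward(p, graph, Xa, ga, Xb, gb)
            return -np.log(probs[np.arange(5), y]).mean()

        _, cache = gcnn_forward(params, graph, Xa, ga, Xb, gb)
        grads, _, _ = gcnn_backward(params, cache, y)
        for key in ("W1_0", "W2_1", "Wd", "bd"):
            g_num = np.zeros_like(params.weights[key])
            it = np.nditer(g_num, flags=["multi_index"])
            while not it.finished:
                idx = it.multi_index
                eps = 1e-6
                p_hi = params.copy()
                p_hi.weights[key][idx] += eps
                p_lo = params.copy()
                p_lo.weights[key][idx] -= eps
                g_num[idx] = (loss_at(p_hi) - loss_at(p_lo)) / (2 * eps)
                it.iternext()
            np.testing.assert_allclose(grads[key], g_num, atol=1e-6, rtol=1e-4)


@pytest.fixture(scope="module")
def toy_problem():
    from .conftest import make_burst_pair_data

    return make_burst_pair_data(11)


class TestTraining:

    def test_loss_decreases_on_separable_data(self, toy_problem):
        wa, wb, y, fs, graph = toy_problem
        cfg = RunConfig(epochs=10, batch_size=16, dropout=0.0)
        _, log = train_local(wa, wb, y, fs, graph, cfg, seed=0)
        assert log.epoch_loss[-1] < log.epoch_loss[0]

    def test_seed_determinism(self, toy_problem):
        wa, wb, y, fs, graph = toy_problem
        cfg = RunConfig(epochs=3, batch_size=16)
        p1, _ = train_local(wa, wb, y, fs, graph, cfg, seed=5)
        p2, _ = train_local(wa, wb, y, fs, graph, cfg, seed=5)
        for k in p1.weights:
            np.testing.assert_array_equal(p1.weights[k], p2.weights[k])

    def test_heldout_accuracy_on_planted_separation(self, toy_problem):
        wa, wb, y, fs, graph = toy_problem
        cfg = RunConfig(epochs=40, batch_size=16, dropout=0.0)
        tr = np.concatenate([np.arange(0, 24), np.arange(30, 54)])
        te = np.concatenate([np.arange(24, 30), np.arange(54, 60)])
        params, _ = train_local(wa[tr], wb[tr], y[tr], fs, graph, cfg, seed=3)
        p = predict_proba(params, graph, wa[te], wb[te], fs)
        assert (((p >= 0.5).astype(int)) == y[te]).mean() >= 0.9

    def test_empty_training_set(self, toy_problem):
        wa, wb, y, fs, graph = toy_problem
        with pytest.raises(ValueError):
            train_local(wa[:0], wb[:0], y[:0], fs, graph, RunConfig(), seed=0)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        params = init_params(seed=9)
        params.scaler_mean = {"0": np.arange(4.0), "1": np.ones(4)}
        params.scaler_scale = {"0": np.full(4, 2.0), "1": np.full(4, 3.0)}
        save_params(params, str(tmp_path / "ckpt"))
        back = load_params(str(tmp_path / "ckpt"))
        assert back.activations == params.activations
        assert back.dropout == params.dropout
        for k in params.weights:
            np.testing.assert_allclose(back.weights[k], params.weights[k])
        for b in ("0", "1"):
            np.testing.assert_allclose(back.scaler_mean[b], params.scaler_mean[b])


class TestBatchFeatures:
    def test_consistent_with_single_segment_encoder(self):
        from epifed.spikes import encode_segment

        rng = np.random.default_rng(13)
        w = rng.standard_normal((6, 50, 3))
        X, gate, _ = batch_node_features(w, fs=25.0, kappa=1.0, offset=0.0, mode="mean")
        for i in range(6):
            rep = encode_segment(w[i], kappa=1.0, mode="mean")
            count, dur = rep.spike_count, rep.spike_duration
            ind = rep.indicator
            np.testing.assert_allclose(X[i, :, 0], count * ind / 2.0)  # runs/s
            np.testing.assert_allclose(X[i, :, 1], dur * ind / 25.0)
            np.testing.assert_allclose(gate[i], rep.node_gate)

    def test_surrogate_gradient_direction(self):
        """Raising the threshold offset lowers spike density; the surrogate
        gradient must carry that sign (on channels whose High/Low indicator
        does not flip across the step)."""
        rng = np.random.default_rng(14)
        w = rng.standard_normal((4, 100, 3))
        X0, g0, dX = batch_node_features(w, 50.0, 1.0, 0.0, mode="mean")
        X1, g1, _ = batch_node_features(w, 50.0, 1.0, 0.05, mode="mean")
        stable = (g0 > 0) & (g1 > 0)  # indicator stayed High
        d_emp = (X1[:, :, 2] - X0[:, :, 2])[stable]
        grad = dX[:, :, 2][stable]
        assert np.all(grad < 0)  # raising the threshold can only drop density
        assert np.all(d_emp <= 0)
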