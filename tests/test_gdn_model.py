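"""Graph-attention forecaster: hand oracle, gradients, invariants, I/O."""

import math

import numpy as np
import pytest

from meagdn import gdn_model as gm
from meagdn.errors import ConfigError, DataError
from meagdn.preprocessing import WindowBatch


def tiny_config(**kw):
    defaults = dict(n_channels=2, window=3, embed_dim=2, hidden_units=2,
                    epochs=1, batch_size=4, seed=0)
    defaults.update(kw)
    return gm.GDNConfig(**defaults)


def make_batch(n, N, w, seed=0):
    rng = np.random.default_rng(seed)
    return WindowBatch(X=rng.standard_normal((n, N, w)),
                       y=rng.standard_normal((n, N)),
                       time_index=np.arange(1, n + 1),
                       segment_id=np.zeros(n, dtype=int), T=w)


def hand_forward(model, x):
    """Pure-Python scalar re-derivation of the forward pass for N=2 channels.

    Returns (alpha, s_hat) computed with explicit loops and math.exp, sharing
    no numpy vector code with the implementation under test.
    """
    cfg = model.config
    N, d, w = cfg.n_channels, cfg.embed_dim, cfg.window
    slope = cfg.leaky_slope
    u = [[sum(model.W[k][t] * x[i][t] for t in range(w)) for k in range(d)]
         for i in range(N)]
    g = [list(model.V[i]) + u[i] for i in range(N)]
    a_src, a_dst = list(model.a[:2 * d]), list(model.a[2 * d:])
    src = [sum(a_src[k] * g[i][k] for k in range(2 * d)) for i in range(N)]
    dst = [sum(a_dst[k] * g[j][k] for k in range(2 * d)) for j in range(N)]
    pi = [[src[i] + dst[j] for j in range(N)] for i in range(N)]
    pi = [[v if v > 0 else slope * v for v in row] for row in pi]
    alpha = []
    for row in pi:
        m = max(row)
        e = [math.exp(v - m) for v in row]
        s = sum(e)
        alpha.append([v / s for v in e])
    z = [[max(0.0, sum(alpha[i][j] * u[j][k] for j in range(N)))
          for k in range(d)] for i in range(N)]
    h = [sum(model.p[k] * model.V[i][k] * z[i][k] for k in range(d))
         for i in range(N)]
    hh = [max(0.0, sum(model.W1[q][i] * h[i] for i in range(N)) + model.b1[q])
          for q in range(cfg.hidden_units)]
    s_hat = [sum(model.W2[i][q] * hh[q] for q in range(cfg.hidden_units))
             + model.b2[i] for i in range(N)]
    return alpha, s_hat


class TestForward:
    def test_matches_pure_python_hand_oracle(self):
        model = gm.GDNModel.initialize(tiny_config(seed=3))
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.standard_normal((2, 3))
            z, alpha = gm.attention_forward(model, x)
            pred = gm.forecast(model, x)
            alpha_o, pred_o = hand_forward(model, x)
            assert np.allclose(alpha, alpha_o, atol=1e-10)
            assert np.allclose(pred, pred_o, atol=1e-10)

    def test_attention_rows_are_stochastic(self):
        cfg = gm.GDNConfig(n_channels=5, window=8, embed_dim=6, hidden_units=3,
                           epochs=1, seed=1)
        model = gm.GDNModel.initialize(cfg)
        rng = np.random.default_rng(2)
        for scale in (1e-3, 1.0, 1e3):
            _, alpha = gm.attention_forward(model, scale * rng.standard_normal((5, 8)))
            assert np.all(alpha >= 0)
            assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-12)

    def test_candidate_set_includes_self(self):
        """No top-k pruning: every coefficient, including the diagonal, is
        strictly positive."""
        model = gm.GDNModel.initialize(tiny_config(n_channels=4, seed=5))
        _, alpha = gm.attention_forward(
            model, np.random.default_rng(0).standard_normal((4, 3)))
        assert np.all(alpha > 0)

    def test_non_finite_input_rejected(self):
        model = gm.GDNModel.initialize(tiny_config())
        x = np.zeros((2, 3))
        x[0, 0] = np.nan
        with pytest.raises(DataError):
            gm.forecast(model, x)

    def test_batch_forecast_matches_single(self):
        model = gm.GDNModel.initialize(tiny_config(seed=9))
        batch = make_batch(7, 2, 3, seed=4)
        preds = gm.batch_forecast(model, batch, chunk=3)
        for k in range(7):
            assert np.allclose(preds[k], gm.forecast(model, batch.X[k]))


class TestGradients:
    def test_backward_matches_finite_differences(self):
        cfg = tiny_config(n_channels=3, window=4, embed_dim=3, hidden_units=2,
                          leaky_slope=0.2, seed=11)
        model = gm.GDNModel.initialize(cfg)
        # move every parameter to O(1) magnitude so no ReLU / LeakyReLU
        # pre-activation sits within finite-difference reach of its kink
        prng = np.random.default_rng(99)
        for name in gm.PARAM_NAMES:
            arr = getattr(model, name)
            arr[...] = prng.uniform(0.2, 1.0, size=arr.shape) * prng.choice(
                [-1.0, 1.0], size=arr.shape)
        batch = make_batch(5, 3, 4, seed=12)
        cache = gm._forward(model, batch.X)
        _, grads = gm._backward(model, cache, batch.y)

        def loss_at(params):
            m = gm.GDNModel(config=cfg, **params)
            c = gm._forward(m, batch.X)
            return np.sum((c["s_hat"] - batch.y) ** 2) / len(batch)

        eps = 1e-6
        rng = np.random.default_rng(13)
        for name in gm.PARAM_NAMES:
            base = model.params()
            flat = base[name].ravel()
            for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                params = {k: v.copy() for k, v in base.items()}
                params[name].ravel()[idx] += eps
                up = loss_at(params)
                params[name].ravel()[idx] -= 2 * eps
                down = loss_at(params)
                numeric = (up - down) / (2 * eps)
                analytic = grads[name].ravel()[idx]
                assert abs(numeric - analytic) <= 1e-6 * max(1.0, abs(numeric)), \
                    (name, idx)


class TestTraining:
    def test_loss_decreases_on_learnable_signal(self):
        """Targets linear in the inputs: training must cut the loss in half."""
        rng = np.random.default_rng(21)
        n, N, w = 400, 3, 8
        X = rng.standard_normal((n, N, w))
        M = rng.standard_normal((N, w)) / w
        y = np.einsum("bnw,nw->bn", X, M)
        batch = WindowBatch(X=X, y=y, time_index=np.arange(1, n + 1),
                            segment_id=np.zeros(n, dtype=int), T=w)
        cfg = gm.GDNConfig(n_channels=N, window=w, embed_dim=8, hidden_units=6,
                           epochs=40, learning_rate=5e-3, batch_size=50, seed=21)
        _, history = gm.train_gdn(batch, cfg)
        assert len(history["train_loss"]) == 40
        assert history["train_loss"][-1] < 0.5 * history["train_loss"][0]

    def test_training_is_deterministic_given_seed(self):
        batch = make_batch(60, 2, 3, seed=30)
        cfg = tiny_config(epochs=2, seed=30)
        m1, h1 = gm.train_gdn(batch, cfg)
        m2, h2 = gm.train_gdn(batch, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        for k in gm.PARAM_NAMES:
            assert np.array_equal(getattr(m1, k), getattr(m2, k))

    def test_empty_batch_rejected(self):
        with pytest.raises(DataError):
            gm.train_gdn(make_batch(0, 2, 3), tiny_config())

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            gm.train_gdn(make_batch(10, 4, 3), tiny_config(n_channels=2))

    def test_validation_history_recorded(self):
        cfg = tiny_config(epochs=3, seed=8)
        _, h = gm.train_gdn(make_batch(40, 2, 3, seed=8), cfg,
                            val_batch=make_batch(10, 2, 3, seed=9))
        assert len(h["val_loss"]) == 3


class TestGraphExtraction:
    def test_one_snapshot_per_target_with_metadata(self):
        model = gm.GDNModel.initialize(tiny_config(n_channels=4, seed=2))
        batch = make_batch(9, 4, 3, seed=2)
        snaps = gm.extract_graphs(model, batch, chunk=4)
        assert len(snaps) == 9
        assert [s.time_index for s in snaps] == list(batch.time_index)

    def test_binarization_rule_above_uniform_strict(self):
        model = gm.GDNModel.initialize(tiny_config(n_channels=4, seed=2))
        batch = make_batch(5, 4, 3, seed=3)
        for snap in gm.extract_graphs(model, batch):
            expected = snap.alpha.T > 1.0 / 4
            np.fill_diagonal(expected, False)
            assert np.array_equal(snap.adjacency, expected)
            assert not snap.adjacency.diagonal().any()

    def test_uniform_attention_gives_empty_graph(self):
        """alpha == 1/N nowhere strictly exceeds the threshold."""
        model = gm.GDNModel.initialize(tiny_config(n_channels=3, seed=0))
        model.a[:] = 0.0  # constant scores -> exactly uniform softmax rows
        batch = make_batch(4, 3, 3, seed=1)
        for snap in gm.extract_graphs(model, batch):
            assert np.allclose(snap.alpha, 1 / 3)
            assert not snap.adjacency.any()

    def test_mean_attention_matches_snapshot_average(self):
        model = gm.GDNModel.initialize(tiny_config(n_channels=3, seed=4))
        batch = make_batch(11, 3, 3, seed=5)
        snaps = gm.extract_graphs(model, batch, chunk=4)
        manual = np.mean([s.alpha for s in snaps], axis=0)
        assert np.allclose(gm.mean_attention(model, batch, chunk=5), manual)


class TestCheckpoint:
    def test_roundtrip_bitwise(self, tmp_path):
        model = gm.GDNModel.initialize(tiny_config(n_channels=3, seed=6))
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = gm.GDNModel.load(path)
        assert loaded.config == model.config
        for k in gm.PARAM_NAMES:
            assert np.array_equal(getattr(loaded, k), getattr(model, k))
        x = np.random.default_rng(0).standard_normal((3, 3))
        assert np.array_equal(gm.forecast(loaded, x), gm.forecast(model, x))


class TestForecastReport:
    def test_perfect_prediction_metrics(self):
        """Evaluating a model against its own predictions: NRMSE 0 and peak
        normalized cross-correlation 1 on every channel."""
        model = gm.GDNModel.initialize(tiny_config(n_channels=3, seed=7))
        batch = make_batch(30, 3, 3, seed=7)
        batch = WindowBatch(X=batch.X, y=gm.batch_forecast(model, batch),
                            time_index=batch.time_index,
                            segment_id=batch.segment_id, T=batch.T)
        rep = gm.evaluate_forecast(model, batch)
        assert np.allclose(rep.nrmse, 0.0, atol=1e-10)
        assert np.allclose(rep.max_xcorr, 1.0, atol=1e-10)

    def test_zero_variance_channel_skipped(self):
        model = gm.GDNModel.initialize(tiny_config(n_channels=2, seed=7))
        batch = make_batch(20, 2, 3, seed=8)
        batch.y[:, 1] = 5.0
        rep = gm.evaluate_forecast(model, batch)
        assert rep.skipped_channels == [1]
        assert np.isnan(rep.nrmse[1]) and np.isfinite(rep.nrmse[0])
        stats = rep.median_mad()
        assert np.isfinite(stats["nrmse_median"])

    def test_embedding_similarity_is_cosine(self):
        V = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 3.0]])
        S = gm.embedding_similarity(V)
        assert np.allclose(np.diag(S), 1.0)
        assert np.isclose(S[0, 1], 0.0)
        assert np.isclose(S[0, 2], np.cos(np.pi / 4))
        with pytest.raises(DataError):
            gm.embedding_similarity(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            gm.GDNConfig(epochs=0)
        with pytest.raises(ConfigError):
            gm.GDNConfig(embed_dim=0)
        with pytest.raises(ConfigError):
            gm.GDNConfig(optimizer="sgd")

    def test_dict_roundtrip(self):
        cfg = gm.GDNConfig(n_channels=4, embed_dim=16, seed=3)
        assert gm.GDNConfig.from_dict(cfg.to_dict()) == cfg
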