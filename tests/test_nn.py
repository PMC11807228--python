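"""Autograd engine and GATv2 model: gradients, oracles, invariances."""

import numpy as np
import pytest

from plignet import ModelConfig, PLIGraph, attention_coefficients, global_pool
from plignet import nn
from plignet.gnn import Batch, Ensemble, GATv2Model, pack_batch
from plignet.nn import Tensor

from _oracles import attention_scalar, gat_layer_scalar, pool_scalar


def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


class TestAutogradGradients:
    """Finite-difference checks for every primitive, composed realistically."""

    def test_dense_chain(self):
        rng = np.random.default_rng(0)
        W = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        b = Tensor(rng.normal(size=(1, 3)), requires_grad=True)
        x = rng.normal(size=(5, 4))

        def loss_value():
            h = nn.relu(Tensor(x) @ W + b)
            return float(nn.mean_all(h * h).data)

        h = nn.relu(Tensor(x) @ W + b)
        loss = nn.mean_all(h * h)
        loss.backward()
        np.testing.assert_allclose(W.grad, _num_grad(loss_value, W.data),
                                   rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(b.grad, _num_grad(loss_value, b.data),
                                   rtol=1e-5, atol=1e-8)

    def test_segment_and_gather_ops(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.normal(size=(6, 3)), requires_grad=True)
        seg = np.array([0, 0, 1, 1, 1, 2])
        idx = np.array([2, 0, 1, 2])

        def build():
            s = nn.segment_sum(x, seg, 3)
            m = nn.segment_max(x, seg, 3)
            g = nn.gather_rows(s + m, idx)
            e = nn.exp(g * Tensor(np.full((4, 3), 0.3)))
            return nn.mean_all(e / (e + Tensor(np.ones((4, 3)))))

        loss = build()
        loss.backward()
        got = x.grad.copy()

        def loss_value():
            return float(build().data)

        np.testing.assert_allclose(got, _num_grad(loss_value, x.data),
                                   rtol=1e-5, atol=1e-8)

    def test_leaky_relu_and_concat(self):
        rng = np.random.default_rng(2)
        a = Tensor(rng.normal(size=(3, 2)), requires_grad=True)
        b = Tensor(rng.normal(size=(3, 4)), requires_grad=True)

        def build():
            return nn.mean_all(
                nn.leaky_relu(nn.concat([a, b], axis=1), 0.2)
                * nn.concat([a, b], axis=1)
            )

        build().backward()
        ga = a.grad.copy()

        def loss_value():
            return float(build().data)

        np.testing.assert_allclose(ga, _num_grad(loss_value, a.data),
                                   rtol=1e-5, atol=1e-8)

    def test_full_model_gradient(self):
        """End-to-end finite-difference check on a tiny model."""
        rng = np.random.default_rng(3)
        g = _random_graph(rng, 4, d=6)
        batch = pack_batch([g])
        cfg = ModelConfig(n_layers=2, n_heads=2, head_dim=3, mlp_hidden=(5,),
                          ensemble_size=1, seed_list=(0,))
        model = GATv2Model(6, 4, cfg, seed=0)
        target = np.array([[1.5]])

        def loss_value():
            return float(nn.mse_loss(model.forward(batch), target).data)

        loss = nn.mse_loss(model.forward(batch), target)
        loss.backward()
        for name in ("l0h0_Ws", "l0h1_b", "l1h0_We", "mlp0_W", "mlp1_b"):
            p = model.params[name]
            num = _num_grad(loss_value, p.data)
            np.testing.assert_allclose(
                p.grad, num, rtol=1e-4, atol=1e-7,
                err_msg=f"gradient mismatch for {name}",
            )


def _random_graph(rng, n_nodes, d=8, p_edge=0.5, label=None):
    feats = rng.normal(size=(n_nodes, d))
    edges = [
        (i, j)
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_edge
    ]
    if not edges and n_nodes > 1:
        edges = [(0, 1)]
    efeat = np.zeros((len(edges), 4))
    for k in range(len(edges)):
        efeat[k, int(rng.integers(4))] = 1.0
    return PLIGraph(feats, np.array(edges).reshape(-1, 2), efeat, label=label)


class TestAttention:
    def _weights(self, rng, din, dh):
        return (rng.normal(size=(din, dh)), rng.normal(size=(din, dh)),
                rng.normal(size=(4, dh)), rng.normal(size=(dh, 1)))

    def test_isolated_node_attends_to_itself(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 5))
        Ws, Wt, We, b = self._weights(rng, 5, 3)
        a = attention_coefficients(
            x, np.array([0]), np.array([0]), np.zeros((1, 4)), Ws, Wt, We, b
        )
        assert a[0] == pytest.approx(1.0)

    def test_identical_neighbors_get_equal_weights(self):
        rng = np.random.default_rng(1)
        xc = rng.normal(size=5)
        xn = rng.normal(size=5)
        x = np.stack([xc, xn, xn])
        src = np.array([1, 2, 0])
        dst = np.array([0, 0, 0])
        ef = np.zeros((3, 4))
        ef[0, 0] = ef[1, 0] = 1.0
        Ws, Wt, We, b = self._weights(rng, 5, 3)
        a = attention_coefficients(x, src, dst, ef, Ws, Wt, We, b)
        assert a[0] == pytest.approx(a[1], rel=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        g = _random_graph(rng, 6)
        batch = pack_batch([g])
        Ws, Wt, We, b = self._weights(rng, 8, 4)
        a = attention_coefficients(
            batch.x, batch.src, batch.dst, batch.edge_attr, Ws, Wt, We, b
        )
        sums = np.zeros(6)
        np.add.at(sums, batch.dst, a)
        np.testing.assert_allclose(sums, np.ones(6), rtol=1e-12)
        assert np.all(a > 0)

    def test_star_graph_matches_scalar_reference(self):
        rng = np.random.default_rng(3)
        # 5-node star: center 0
        feats = rng.normal(size=(5, 6))
        edges = np.array([(0, k) for k in range(1, 5)])
        efeat = np.zeros((4, 4))
        efeat[np.arange(4), rng.integers(0, 4, 4)] = 1.0
        g = PLIGraph(feats, edges, efeat)
        batch = pack_batch([g])
        Ws, Wt, We, b = self._weights(rng, 6, 3)
        fast = attention_coefficients(
            batch.x, batch.src, batch.dst, batch.edge_attr, Ws, Wt, We, b
        )
        slow = attention_scalar(
            batch.x, list(zip(batch.src, batch.dst)), batch.edge_attr,
            Ws, Wt, We, b,
        )
        np.testing.assert_allclose(fast, slow, rtol=1e-6)

    def test_zero_attention_vector_gives_uniform_weights(self):
        rng = np.random.default_rng(4)
        g = _random_graph(rng, 5)
        batch = pack_batch([g])
        Ws, Wt, We, _ = self._weights(rng, 8, 3)
        a = attention_coefficients(
            batch.x, batch.src, batch.dst, batch.edge_attr,
            Ws, Wt, We, np.zeros((3, 1)),
        )
        degree = np.bincount(batch.dst, minlength=5)
        np.testing.assert_allclose(a, 1.0 / degree[batch.dst], rtol=1e-12)


class TestForward:
    def test_single_layer_matches_scalar_oracle_on_path_graph(self):
        rng = np.random.default_rng(5)
        feats = rng.normal(size=(3, 7))
        edges = np.array([(0, 1), (1, 2)])
        efeat = np.zeros((2, 4))
        efeat[:, 0] = 1.0
        g = PLIGraph(feats, edges, efeat)
        batch = pack_batch([g])
        cfg = ModelConfig(n_layers=1, n_heads=2, head_dim=4,
                          mlp_hidden=(3,), ensemble_size=1, seed_list=(0,))
        model = GATv2Model(7, 4, cfg, seed=1)
        x = nn.Tensor(batch.x)
        e = nn.Tensor(batch.edge_attr)
        fast = model._layer(0, x, batch, e).data
        heads = [
            tuple(model.params[f"l0h{h}_{k}"].data for k in ("Ws", "Wt", "We", "b"))
            for h in range(2)
        ]
        slow = gat_layer_scalar(
            batch.x, list(zip(batch.src, batch.dst)), batch.edge_attr, heads
        )
        np.testing.assert_allclose(fast, slow, rtol=1e-5, atol=1e-8)

    def test_permutation_equivariance_of_prediction(self):
        rng = np.random.default_rng(6)
        g = _random_graph(rng, 6)
        cfg = ModelConfig(n_layers=2, n_heads=2, head_dim=4, mlp_hidden=(8,),
                          ensemble_size=1, seed_list=(0,))
        model = GATv2Model(8, 4, cfg, seed=2)
        ref = model.predict([g])[0]
        perm = rng.permutation(6)
        inv = np.argsort(perm)
        g2 = PLIGraph(
            g.node_features[perm],
            inv[g.edges],
            g.edge_features,
        )
        assert model.predict([g2])[0] == pytest.approx(ref, rel=1e-9)

    def test_width_mismatch_names_the_problem(self):
        rng = np.random.default_rng(7)
        g = _random_graph(rng, 3, d=5)
        cfg = ModelConfig(n_layers=1, n_heads=1, head_dim=2, mlp_hidden=(2,),
                          ensemble_size=1, seed_list=(0,))
        model = GATv2Model(9, 4, cfg, seed=0)
        with pytest.raises(ValueError, match="AEV"):
            model.predict([g])

    def test_inference_is_deterministic(self):
        rng = np.random.default_rng(8)
        g = _random_graph(rng, 5)
        cfg = ModelConfig(n_layers=2, n_heads=3, head_dim=4, mlp_hidden=(8,),
                          ensemble_size=1, seed_list=(0,))
        model = GATv2Model(8, 4, cfg, seed=3)
        assert model.predict([g])[0] == model.predict([g])[0]


class TestPooling:
    def test_single_node_pool_is_duplicated_features(self):
        x = np.array([[1.0, -2.0, 3.0]])
        np.testing.assert_array_equal(global_pool(x), [1, -2, 3, 1, -2, 3])

    def test_node_duplication_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(4, 5))
        doubled = np.vstack([x, x])
        np.testing.assert_allclose(global_pool(doubled), global_pool(x),
                                   rtol=1e-12)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(7, 6))
        np.testing.assert_allclose(global_pool(x), pool_scalar(x), rtol=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            global_pool(np.zeros((0, 4)))


class TestEnsemble:
    def _models(self, n, rng):
        cfg = ModelConfig(n_layers=1, n_heads=1, head_dim=3, mlp_hidden=(4,),
                          ensemble_size=1, seed_list=(0,))
        return [GATv2Model(8, 4, cfg, seed=k) for k in range(n)]

    def test_mean_is_arithmetic_mean_of_members(self):
        rng = np.random.default_rng(11)
        g = _random_graph(rng, 4)
        ens = Ensemble(self._models(5, rng))
        pred = ens.predict([g])
        assert pred.mean_pk[0] == pytest.approx(pred.member_pks[:, 0].mean())

    def test_single_member_ensemble(self):
        rng = np.random.default_rng(12)
        g = _random_graph(rng, 4)
        members = self._models(1, rng)
        pred = Ensemble(members).predict([g])
        assert pred.mean_pk[0] == pytest.approx(members[0].predict([g])[0])

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        g = _random_graph(rng, 5)
        ens = Ensemble(self._models(3, rng))
        ref = ens.predict([g]).mean_pk
        ens.save(str(tmp_path / "ens"))
        back = Ensemble.load(str(tmp_path / "ens"))
        np.testing.assert_array_equal(back.predict([g]).mean_pk, ref)
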