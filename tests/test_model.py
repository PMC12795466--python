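import numpy as np
import pytest

from dagformer._autodiff import Tensor
from dagformer.graphs import build_cell_graph, symmetrize_normalize
from dagformer.model import (DAGFormer, GraphTransformerLayer, ModelConfig,
                             gradient_reversal, inner_product_decode,
                             input_projection, sparse_attention,
                             transformer_block)


def tiny_config(**kw):
    defaults = dict(d_h=8, n_heads=2, d_k=4, ffn_hidden=16,
                    discriminator_hidden=8, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


def random_graph(n, rng, p=0.4):
    A = (rng.random((n, n)) < p).astype(float)
    np.fill_diagonal(A, 0)
    return symmetrize_normalize(A)


def dense_attention_oracle(H, graph, W_Q, W_K, W_V):
    """Explicit per-node, per-neighbor recomputation of sparse attention."""
    n, _ = H.shape
    heads = []
    for k in range(W_Q.shape[0]):
        Q, K, V = H @ W_Q[k], H @ W_K[k], H @ W_V[k]
        out = np.zeros((n, W_Q.shape[2]))
        for i in range(n):
            nbrs = [j for j in range(n) if graph.binary[i, j] > 0]
            logits = np.array([graph.adjacency[i, j] * (Q[i] @ K[j])
                               for j in nbrs])
            w = np.exp(logits - logits.max())
            w /= w.sum()
            out[i] = sum(wj * V[j] for wj, j in zip(w, nbrs))
        heads.append(out)
    return np.hstack(heads)


class TestInputProjection:
    def test_zero_input_and_zero_weights(self):
        W = np.zeros((3, 2))
        assert (input_projection(np.zeros((2, 3)), W).data == 0).all()
        assert (input_projection(np.ones((2, 3)), W).data == 0).all()

    def test_matches_manual_matmul_with_relu(self):
        X = np.array([[1.0, -1.0, 2.0], [0.5, 0.0, -2.0]])
        W = np.array([[1.0, -1.0], [2.0, 0.5], [-1.0, 1.0]])
        expected = np.maximum(X @ W, 0.0)
        np.testing.assert_allclose(input_projection(X, W).data, expected)


class TestSparseAttention:
    def test_single_neighbor_gets_weight_one(self, rng):
        # node 1 connected only to node 0 (plus self-loops everywhere)
        A = np.zeros((3, 3))
        A[1, 0] = 1
        graph = symmetrize_normalize(A)
        cfg = tiny_config()
        layer = GraphTransformerLayer(cfg, np.random.default_rng(0))
        H = Tensor(rng.normal(size=(3, cfg.d_h)))
        out = sparse_attention(H, graph, layer.W_Q, layer.W_K, layer.W_V)
        oracle = dense_attention_oracle(H.data, graph, layer.W_Q.data,
                                        layer.W_K.data, layer.W_V.data)
        np.testing.assert_allclose(out.data, oracle, atol=1e-10)

    def test_attention_weights_sum_to_one_per_neighbor_set(self, rng):
        graph = random_graph(7, rng)
        cfg = tiny_config()
        layer = GraphTransformerLayer(cfg, np.random.default_rng(1))
        H = Tensor(rng.normal(size=(7, cfg.d_h)))
        Q = (H @ layer.W_Q).data
        K = (H @ layer.W_K).data
        logits = graph.adjacency * (Q @ K.swapaxes(-1, -2))
        mask = graph.binary > 0
        for k in range(cfg.n_heads):
            for i in range(7):
                row = logits[k, i][mask[i]]
                w = np.exp(row - row.max())
                assert np.isclose((w / w.sum()).sum(), 1.0)

    @pytest.mark.parametrize("n_heads,d_k", [(1, 8), (2, 4), (4, 2)])
    def test_matches_dense_neighbor_loop_oracle(self, n_heads, d_k, rng):
        cfg = tiny_config(n_heads=n_heads, d_k=d_k)
        for trial in range(5):
            local = np.random.default_rng(trial)
            n = int(local.integers(4, 20))
            graph = random_graph(n, local)
            layer = GraphTransformerLayer(cfg, local)
            H = Tensor(local.normal(size=(n, cfg.d_h)))
            out = sparse_attention(H, graph, layer.W_Q, layer.W_K, layer.W_V)
            oracle = dense_attention_oracle(H.data, graph, layer.W_Q.data,
                                            layer.W_K.data, layer.W_V.data)
            np.testing.assert_allclose(out.data, oracle, atol=1e-5)


class TestTransformerBlock:
    def test_literal_ffn_zero_weights_give_zero_output(self, rng):
        cfg = tiny_config(literal_ffn=True)
        layer = GraphTransformerLayer(cfg, np.random.default_rng(0))
        layer.W1.data[...] = 0
        layer.W2.data[...] = 0
        layer.b1.data[...] = 0
        layer.b2.data[...] = 0
        graph = random_graph(5, rng)
        H = Tensor(rng.normal(size=(5, cfg.d_h)))
        out = transformer_block(H, graph, layer, training=True)
        np.testing.assert_array_equal(out.data, np.zeros((5, cfg.d_h)))

    def test_shape_preserved_across_stacked_layers(self, rng):
        cfg = tiny_config(n_layers=3)
        graph = random_graph(6, rng)
        model = DAGFormer(10, cfg)
        H = model.encode(Tensor(rng.normal(size=(6, 10))), graph, "shared")
        assert H.shape == (6, cfg.d_h)

    def test_matches_stepwise_hand_computation(self, rng):
        # dropout off: the oracle reproduces the deterministic block math
        cfg = tiny_config(dropout=0.0)
        layer = GraphTransformerLayer(cfg, np.random.default_rng(3))
        graph = random_graph(4, rng)
        H = rng.normal(size=(4, cfg.d_h))
        out = transformer_block(Tensor(H), graph, layer, training=True).data

        attn = dense_attention_oracle(H, graph, layer.W_Q.data,
                                      layer.W_K.data, layer.W_V.data)
        pre = attn + H
        mu, var = pre.mean(axis=0), pre.var(axis=0)
        hhat = (pre - mu) / np.sqrt(var + layer.bn1.eps)
        ffn = np.maximum(hhat @ layer.W1.data + layer.b1.data, 0) \
            @ layer.W2.data + layer.b2.data
        np.testing.assert_allclose(out, ffn, atol=1e-8)

    def test_batch_of_one_in_training_mode_raises(self, rng):
        cfg = tiny_config()
        layer = GraphTransformerLayer(cfg, np.random.default_rng(0))
        graph = symmetrize_normalize(np.zeros((1, 1)))
        with pytest.raises(ValueError, match="eval mode"):
            transformer_block(Tensor(rng.normal(size=(1, cfg.d_h))), graph,
                              layer, training=True)


class TestEncoders:
    def test_shared_encoder_is_weight_tied_across_domains(self):
        model = DAGFormer(12, tiny_config())
        # same object serves both domains: mutating it changes both
        assert model.encode.__self__ is model
        ps = model.encoder_shared.parameters()
        assert all(p is q for p, q in zip(ps, model.encoder_shared.parameters()))

    def test_private_encoders_have_disjoint_parameters(self, rng):
        model = DAGFormer(12, tiny_config())
        src_ids = {id(p) for p in model.encoder_private_source.parameters()}
        tgt_ids = {id(p) for p in model.encoder_private_target.parameters()}
        shared_ids = {id(p) for p in model.encoder_shared.parameters()}
        assert src_ids.isdisjoint(tgt_ids)
        assert src_ids.isdisjoint(shared_ids)
        # mutating a source-private weight leaves the target encoder intact
        before = model.encoder_private_target.W_proj.data.copy()
        model.encoder_private_source.W_proj.data += 100.0
        np.testing.assert_array_equal(
            model.encoder_private_target.W_proj.data, before)

    def test_deterministic_under_fixed_seed(self, rng):
        graph = random_graph(6, rng)
        X = rng.normal(size=(6, 12))
        outs = []
        for _ in range(2):
            model = DAGFormer(12, tiny_config(seed=9))
            outs.append(model.encode(Tensor(X), graph, "shared").data)
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_permutation_equivariance_in_eval_mode(self, rng):
        n = 8
        graph = random_graph(n, rng)
        X = rng.normal(size=(n, 12))
        model = DAGFormer(12, tiny_config())
        out = model.encode(Tensor(X), graph, "shared").data

        perm = rng.permutation(n)
        from dagformer.graphs import CellGraph
        gp = CellGraph(graph.adjacency[np.ix_(perm, perm)],
                       graph.binary[np.ix_(perm, perm)],
                       [sorted(int(np.where(perm == j)[0][0])
                               for j in graph.neighbor_lists[i])
                        for i in perm],
                       graph.method, graph.params)
        out_p = model.encode(Tensor(X[perm]), gp, "shared").data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-8)


class TestDecodersAndHeads:
    def test_zero_embedding_gives_half_probabilities(self):
        P = inner_product_decode(np.zeros((3, 4)), np.zeros((3, 4)))
        np.testing.assert_allclose(P.data, 0.5)

    def test_reconstruction_symmetric(self, rng):
        P = inner_product_decode(rng.normal(size=(5, 4)),
                                 rng.normal(size=(5, 4)))
        np.testing.assert_allclose(P.data, P.data.T, atol=1e-12)
        assert (P.data > 0).all() and (P.data < 1).all()

    def test_matches_hand_computed_sigmoid_dot_products(self):
        H_pr = np.array([[1.0, 0.0], [0.0, 1.0]])
        H_sh = np.array([[0.5, 0.0], [0.0, -0.5]])
        Z = np.hstack([H_pr, H_sh])
        expected = 1.0 / (1.0 + np.exp(-(Z @ Z.T)))
        P = inner_product_decode(H_pr, H_sh)
        np.testing.assert_allclose(P.data, expected, atol=1e-9)

    def test_grl_forward_identity_and_scaled_sign_flip(self):
        x = Tensor(np.array([2.0]), requires_grad=True)
        out = gradient_reversal(x, 1.0)
        np.testing.assert_array_equal(out.data, x.data)
        out.sum().backward()
        np.testing.assert_array_equal(x.grad, [-1.0])

        x2 = Tensor(np.array([2.0]), requires_grad=True)
        gradient_reversal(x2, 0.0).sum().backward()
        np.testing.assert_array_equal(x2.grad, [0.0])

    def test_zeroed_heads_output_half(self):
        model = DAGFormer(6, tiny_config())
        for p in model.discriminator.parameters():
            p.data[...] = 0
        for p in model.predictor.parameters():
            p.data[...] = 0
        H = np.ones((4, model.config.d_h))
        np.testing.assert_allclose(model.discriminate_domain(H).data, 0.5)
        np.testing.assert_allclose(model.predict_response(H).data, 0.5)

    def test_predictor_fixed_weights_hand_computation(self):
        model = DAGFormer(6, tiny_config())
        model.predictor.W.data[...] = 0
        model.predictor.W.data[0, 0] = 1.0
        model.predictor.b.data[...] = -0.5
        H = np.zeros((2, model.config.d_h))
        H[0, 0] = 1.0
        expected = 1.0 / (1.0 + np.exp(-np.array([0.5, -0.5])))
        np.testing.assert_allclose(model.predict_response(H).data, expected,
                                   atol=1e-9)

    def test_probabilities_strictly_inside_unit_interval(self):
        model = DAGFormer(6, tiny_config())
        H = np.full((3, model.config.d_h), 1e4)  # saturates the sigmoid
        psi = model.predict_response(H).data
        assert (psi > 0).all() and (psi < 1).all()


class TestGRLFiniteDifference:
    def test_grl_gradient_is_minus_lambda_times_plain_gradient(self):
        """Scalar toy network: loss = sigmoid(w*x) through a GRL."""
        lam = 0.7
        x, w0 = 1.3, 0.4

        def grad_with(lam_or_none):
            w = Tensor(np.array([w0]), requires_grad=True)
            h = w * x
            if lam_or_none is not None:
                h = gradient_reversal(h, lam_or_none)
            loss = h.sigmoid().sum()
            loss.backward()
            return w.grad[0]

        g_plain = grad_with(None)
        g_grl = grad_with(lam)
        assert g_grl == pytest.approx(-lam * g_plain, rel=1e-10)

        # and the plain gradient itself matches central differences
        eps = 1e-6
        import math
        f = lambda w: 1 / (1 + math.exp(-w * x))
        num = (f(w0 + eps) - f(w0 - eps)) / (2 * eps)
        assert g_plain == pytest.approx(num, rel=1e-4)


class TestPersistence:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path, rng):
        cfg = tiny_config()
        model = DAGFormer(10, cfg)
        graph = random_graph(6, rng)
        X = rng.normal(size=(6, 10))
        before = model.predict_response(
            model.encode(Tensor(X), graph, "shared")).data
        model.save(tmp_path / "ckpt")
        loaded = DAGFormer.load(tmp_path / "ckpt")
        after = loaded.predict_response(
            loaded.encode(Tensor(X), graph, "shared")).data
        np.testing.assert_array_equal(before, after)
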