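import numpy as np
import pytest

from egolink.autodiff import Tensor
from egolink.egonet import EgonetBatch, egonet_batch, extract_egonet
from egolink.graph import ProteinGraph
from egolink.model import (EdgeClassifier, ModelConfig, edge_index_from_graph,
                           fuse, gin_update)
from egolink.nn import MLP
from tests.conftest import random_multigraph


def small_model(graph, hidden=16, mode="combined", seed=0, k=1):
    cfg = ModelConfig(input_dim=graph.features.shape[1], hidden_dim=hidden,
                      mode=mode, seed=seed, k=k,
                      dropout_local=0.0, dropout_global=0.0)
    return EdgeClassifier(cfg).eval()


# -- reference (unbatched / dense) implementations -------------------------

def dense_gin_oracle(X, graph, mlp_weights, eps):
    n = X.shape[0]
    A = np.zeros((n, n))
    for i, j in graph.edges:
        A[i, j] = A[j, i] = 1.0
    h = (A + (1.0 + eps) * np.eye(n)) @ X
    (w1, b1), (w2, b2) = mlp_weights
    return np.maximum(h @ w1 + b1, 0.0) @ w2 + b2


def mlp_weights(mlp: MLP):
    return [(l.weight.data, l.bias.data) for l in mlp.layers]


def apply_mlp(x, weights):
    for w, b in weights[:-1]:
        x = np.maximum(x @ w + b, 0.0)
    w, b = weights[-1]
    return x @ w + b


def gate_oracle(onehot, gate):
    h = np.maximum(onehot @ gate.lin1.weight.data + gate.lin1.bias.data, 0.0)
    z = h @ gate.lin2.weight.data + gate.lin2.bias.data
    return 1.0 / (1.0 + np.exp(-z))


def local_branches_oracle(model, graph, k):
    """Per-egonet loop evaluation of the local encoder (eval mode)."""
    enc = model.local_enc
    Xe = graph.features @ model.embed.weight.data + model.embed.bias.data
    eps = float(enc.epsilon.data) if isinstance(enc.epsilon, Tensor) \
        else enc.epsilon
    kw = mlp_weights(enc.gin_mlp)
    n = graph.n_proteins
    half = enc.gin_mlp.layers[-1].weight.data.shape[1]
    sub = np.zeros((n, half))
    cen = np.zeros((n, half))
    eye = np.eye(2 * k + 1)
    g0 = gate_oracle(eye[0][None, :], enc.gate)[0]
    for v in range(n):
        ego = extract_egonet(graph, v, k)
        m = ego.size
        A = np.zeros((m, m))
        for a, b in ego.induced_edges:
            A[a, b] = A[b, a] = 1.0
        Xm = Xe[ego.members]
        h = apply_mlp((A + (1.0 + eps) * np.eye(m)) @ Xm, kw)
        gates = gate_oracle(eye[np.clip(ego.dist_to_center, 0, 2 * k)],
                            enc.gate)
        sub[v] = (gates * h).sum(axis=0)
        cen[v] = g0 * h[0]  # center is member 0
    return sub, cen


# -- gin_update ------------------------------------------------------------

class TestGinUpdate:
    def test_no_edges_is_pointwise_mlp(self):
        rng = np.random.default_rng(0)
        mlp = MLP([3, 5, 4], rng)
        X = rng.normal(size=(6, 3))
        out = gin_update(Tensor(X), np.zeros((2, 0), dtype=np.intp), mlp, 0.0)
        np.testing.assert_allclose(out.data,
                                   apply_mlp(X, mlp_weights(mlp)), atol=1e-12)

    def test_vertex_transitive_graph_identical_outputs(self):
        # cycle graph with identical features: all outputs equal
        n = 6
        edges = [[i, (i + 1) % n] for i in range(n)]
        labels = np.zeros((n, 7), dtype=np.uint8)
        labels[:, 0] = 1
        g = ProteinGraph(protein_ids=[str(i) for i in range(n)],
                         edges=np.sort(edges, axis=1), labels=labels)
        rng = np.random.default_rng(1)
        mlp = MLP([3, 5, 4], rng)
        X = np.tile(rng.normal(size=(1, 3)), (n, 1))
        out = gin_update(Tensor(X), edge_index_from_graph(g), mlp, 0.5)
        np.testing.assert_allclose(out.data, np.tile(out.data[:1], (n, 1)),
                                   atol=1e-10)

    @pytest.mark.parametrize("eps", [0.0, 0.3])
    def test_matches_dense_adjacency_oracle(self, eps):
        g = random_multigraph(6, 0.5, seed=2)
        rng = np.random.default_rng(3)
        mlp = MLP([4, 8, 5], rng)
        out = gin_update(Tensor(g.features), edge_index_from_graph(g), mlp, eps)
        expected = dense_gin_oracle(g.features, g, mlp_weights(mlp), eps)
        np.testing.assert_allclose(out.data, expected, atol=1e-10)


# -- global encoder --------------------------------------------------------

class TestGlobalEncoder:
    def test_eval_deterministic(self, random_graph):
        model = small_model(random_graph, mode="global")
        ei = edge_index_from_graph(random_graph)
        a = model.vertex_embeddings(random_graph.features, ei, None).data
        b = model.vertex_embeddings(random_graph.features, ei, None).data
        np.testing.assert_array_equal(a, b)

    def test_trainmode_batchnorm_stats(self, random_graph):
        model = small_model(random_graph, mode="global").train()
        ei = edge_index_from_graph(random_graph)
        out = model.vertex_embeddings(random_graph.features, ei, None).data
        # batchnorm with gamma=1, beta=0: column means ~0; variances ~1
        # except for degenerate (dead-ReLU) columns, which normalize to 0
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-8)
        v = out.var(axis=0)
        assert np.all((np.abs(v - 1.0) < 1e-3) | (v < 1e-3))
        assert np.any(np.abs(v - 1.0) < 1e-3)

    def test_permutation_equivariant_rows(self, random_graph):
        model = small_model(random_graph, mode="global")
        ei = edge_index_from_graph(random_graph)
        H = model.vertex_embeddings(random_graph.features, ei, None).data
        perm = np.random.default_rng(0).permutation(random_graph.n_proteins)
        inv = np.argsort(perm)
        pg = random_multigraph(30, 0.15, seed=0)
        pg.edges = np.sort(perm[random_graph.edges], axis=1)
        pg.features = random_graph.features[inv]
        Hp = model.vertex_embeddings(pg.features, edge_index_from_graph(pg),
                                     None).data
        np.testing.assert_allclose(Hp[perm], H, atol=1e-9)


# -- local (ego-subgraph) encoder ------------------------------------------

def manual_batch(graph, k):
    egos = [extract_egonet(graph, v, k) for v in range(graph.n_proteins)]
    offsets = np.cumsum([0] + [e.size for e in egos])
    union = [e.induced_edges + offsets[v] for v, e in enumerate(egos)
             if e.induced_edges.size]
    return EgonetBatch(
        k=k, egonets=egos,
        slot_vertex=np.concatenate([e.members for e in egos]),
        slot_center=np.concatenate(
            [np.full(e.size, e.center, dtype=np.intp) for e in egos]),
        slot_dist=np.concatenate([e.dist_to_center for e in egos]),
        center_slot=offsets[:-1].copy(),
        offsets=np.asarray(offsets),
        union_edges=(np.concatenate(union) if union
                     else np.zeros((0, 2), dtype=np.intp)))


class TestLocalEncoder:
    def test_k0_singletons_double_gated_embedding(self, random_graph):
        model = small_model(random_graph, mode="local", k=0)
        batch = manual_batch(random_graph, 0)
        Xe = (random_graph.features @ model.embed.weight.data
              + model.embed.bias.data)
        sub, cen = model.local_enc.branches(
            Tensor(Xe), batch, random_graph.n_proteins)
        np.testing.assert_allclose(sub.data, cen.data, atol=1e-12)
        h = apply_mlp(Xe, mlp_weights(model.local_enc.gin_mlp))
        g0 = gate_oracle(np.eye(1), model.local_enc.gate)[0]
        np.testing.assert_allclose(sub.data + cen.data, 2 * g0 * h, atol=1e-10)

    def test_zero_gate_weights_half_sum(self, random_graph):
        model = small_model(random_graph, mode="local", k=1)
        gate = model.local_enc.gate
        for lin in (gate.lin1, gate.lin2):
            lin.weight.data[:] = 0.0
            lin.bias.data[:] = 0.0
        batch = egonet_batch(random_graph, 1)
        Xe = (random_graph.features @ model.embed.weight.data
              + model.embed.bias.data)
        sub, _ = model.local_enc.branches(Tensor(Xe), batch,
                                          random_graph.n_proteins)
        h = np.zeros_like(sub.data)
        hk = apply_mlp(Xe, mlp_weights(model.local_enc.gin_mlp))
        # with zero gates sigmoid = 0.5 -> subgraph branch = 0.5 * sum_j h_j
        full = gin_update(Tensor(Xe).take(batch.slot_vertex),
                          np.stack([np.concatenate([batch.union_edges[:, 0],
                                                    batch.union_edges[:, 1]]),
                                    np.concatenate([batch.union_edges[:, 1],
                                                    batch.union_edges[:, 0]])]),
                          model.local_enc.gin_mlp, 0.0).data
        np.add.at(h, batch.slot_center, full)
        np.testing.assert_allclose(sub.data, 0.5 * h, atol=1e-10)

    @pytest.mark.parametrize("k", [1, 2])
    def test_batched_equals_unbatched_oracle(self, k):
        graph = random_multigraph(12, 0.3, seed=6)
        model = small_model(graph, mode="local", k=k)
        batch = egonet_batch(graph, k)
        Xe = Tensor(graph.features @ model.embed.weight.data
                    + model.embed.bias.data)
        sub, cen = model.local_enc.branches(Xe, batch, graph.n_proteins)
        sub_ref, cen_ref = local_branches_oracle(model, graph, k)
        np.testing.assert_allclose(sub.data, sub_ref, atol=1e-8)
        np.testing.assert_allclose(cen.data, cen_ref, atol=1e-8)

    def test_path_graph_fixed_weights(self, path_graph):
        model = small_model(path_graph, mode="local", k=1)
        batch = egonet_batch(path_graph, 1)
        Xe = Tensor(path_graph.features @ model.embed.weight.data
                    + model.embed.bias.data)
        sub, cen = model.local_enc.branches(Xe, batch, 5)
        sub_ref, cen_ref = local_branches_oracle(model, path_graph, 1)
        np.testing.assert_allclose(sub.data, sub_ref, atol=1e-10)
        np.testing.assert_allclose(cen.data, cen_ref, atol=1e-10)


# -- fuse / head -----------------------------------------------------------

class TestFuseAndHead:
    def test_fuse_widths(self):
        a, b = Tensor(np.ones((4, 3))), Tensor(np.zeros((4, 2)))
        assert fuse(a, b).shape == (4, 5)
        with pytest.raises(ValueError):
            fuse(Tensor(np.ones((4, 3))), Tensor(np.ones((5, 3))))

    def test_zero_local_part_keeps_global(self):
        g = Tensor(np.arange(12.0).reshape(4, 3))
        out = fuse(g, Tensor(np.zeros((4, 3))))
        np.testing.assert_array_equal(out.data[:, :3], g.data)
        np.testing.assert_array_equal(out.data[:, 3:], 0.0)

    def test_endpoint_swap_invariance(self, random_graph):
        model = small_model(random_graph)
        ei = edge_index_from_graph(random_graph)
        ego = egonet_batch(random_graph, 1)
        H = model.vertex_embeddings(random_graph.features, ei, ego)
        p1 = model.predict_edges(H, random_graph.edges).data
        swapped = random_graph.edges[:, ::-1]
        p2 = model.predict_edges(H, swapped).data
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_zero_embedding_row_gives_bias_only(self, random_graph):
        model = small_model(random_graph)
        H = Tensor(np.zeros((random_graph.n_proteins, 16)))
        p = model.predict_edges(H, random_graph.edges).data
        expected = 1.0 / (1.0 + np.exp(-model.head.bias.data))
        np.testing.assert_allclose(p, np.tile(expected, (p.shape[0], 1)),
                                   atol=1e-12)

    def test_per_edge_loop_oracle(self, random_graph):
        model = small_model(random_graph)
        rng = np.random.default_rng(8)
        H = Tensor(rng.normal(size=(random_graph.n_proteins, 16)))
        p = model.predict_edges(H, random_graph.edges).data
        for e, (i, j) in enumerate(random_graph.edges):
            z = (H.data[int(i)] * H.data[int(j)]) @ model.head.weight.data \
                + model.head.bias.data
            np.testing.assert_allclose(p[e], 1 / (1 + np.exp(-z)), atol=1e-12)

    def test_invalid_edge_index(self, random_graph):
        model = small_model(random_graph)
        H = Tensor(np.zeros((random_graph.n_proteins, 16)))
        with pytest.raises(IndexError):
            model.predict_edges(H, np.array([[0, 999]]))


# -- end-to-end properties -------------------------------------------------

class TestEndToEnd:
    def test_probabilities_in_open_interval(self):
        for hidden, mode in [(8, "combined"), (16, "global"), (16, "local")]:
            g = random_multigraph(20, 0.2, seed=hidden)
            model = small_model(g, hidden=hidden, mode=mode)
            ei = edge_index_from_graph(g)
            ego = egonet_batch(g, 1) if mode != "global" else None
            p = model(g.features, ei, ego, g.edges).data
            assert np.all((p > 0) & (p < 1))
            assert np.all(np.isfinite(p))

    def test_full_permutation_equivariance(self):
        graph = random_multigraph(18, 0.25, seed=3)
        model = small_model(graph)
        ei = edge_index_from_graph(graph)
        ego = egonet_batch(graph, 1)
        p = model(graph.features, ei, ego, graph.edges).data

        perm = np.random.default_rng(4).permutation(graph.n_proteins)
        inv = np.argsort(perm)
        pg = random_multigraph(18, 0.25, seed=3)
        pg.edges = np.sort(perm[graph.edges], axis=1)
        pg.features = graph.features[inv]
        ego_p = egonet_batch(pg, 1)
        pp = model(pg.features, edge_index_from_graph(pg), ego_p,
                   perm[graph.edges]).data
        np.testing.assert_allclose(pp, p, atol=1e-6)

    def test_ablation_modes_change_head_width(self, random_graph):
        for mode, width in [("combined", 16), ("global", 8), ("local", 8)]:
            model = small_model(random_graph, hidden=16, mode=mode)
            assert model.head.weight.data.shape[0] == width


class TestModelConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(input_dim=0)
        with pytest.raises(ValueError):
            ModelConfig(input_dim=4, dropout_local=1.0)
        with pytest.raises(ValueError):
            ModelConfig(input_dim=4, mode="both")

    def test_round_trip_dict(self):
        cfg = ModelConfig(input_dim=4, hidden_dim=32, k=2, mode="local")
        assert ModelConfig(**cfg.to_dict()) == cfg
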