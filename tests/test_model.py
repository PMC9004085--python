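import numpy as np
import pytest

from hgdti import (
    HGDTIClassifier,
    aggregate_homogeneous,
    bce_loss,
    build_dataset,
    fuse_attention,
    predict_pair,
)
from hgdti._network import HGDTINetwork, leaky_relu, train_network
from hgdti.features import build_node_content

from conftest import manual_mats, write_dtinet_dir


class TestAggregateHomogeneous:
    def test_single_neighbor_is_identity(self):
        f1 = np.random.default_rng(0).normal(size=(1, 8))
        assert np.allclose(aggregate_homogeneous(f1, [2.5]), f1[0])

    def test_weighted_mean(self):
        a, b = np.ones(4), np.full(4, 5.0)
        out = aggregate_homogeneous(np.stack([a, b]), [1.0, 3.0])
        assert np.allclose(out, (a + 3 * b) / 4)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        f1 = rng.normal(size=(6, 16))
        w = rng.random(6) + 0.1
        ref = sum(w[i] * f1[i] for i in range(6)) / w.sum()
        assert np.allclose(aggregate_homogeneous(f1, w), ref, atol=1e-12)

    def test_identical_neighbors_reproduce_themselves(self):
        c = np.random.default_rng(2).normal(size=12)
        f1 = np.tile(c, (5, 1))
        w = np.random.default_rng(3).random(5) + 0.01
        assert np.allclose(aggregate_homogeneous(f1, w), c, atol=1e-12)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            aggregate_homogeneous(np.ones((3, 4)), np.zeros(3))


class TestFuseAttention:
    def test_equal_scores_give_uniform_weights(self):
        dim = 6
        C = np.zeros(dim)  # all candidate scores collapse to u . [cand, C] = 0
        G = np.zeros((3, dim))
        _, alphas = fuse_attention(C, G, u=np.random.default_rng(0).normal(size=2 * dim))
        assert np.allclose(alphas, 1 / 4)

    def test_no_neighbors_returns_self_content(self):
        rng = np.random.default_rng(1)
        C = rng.normal(size=10)
        F, alphas = fuse_attention(C, None, u=rng.normal(size=20))
        assert np.allclose(F, C)
        assert np.allclose(alphas, [1.0])

    def test_softmax_weights_recomputed_by_hand(self):
        rng = np.random.default_rng(2)
        dim = 8
        C = rng.normal(size=dim)
        G = rng.normal(size=(3, dim))
        u = rng.normal(size=2 * dim)
        F, alphas = fuse_attention(C, G, u, slope=0.2)
        cands = np.vstack([C, G])
        scores = [leaky_relu(np.dot(u, np.concatenate([c, C])), 0.2) for c in cands]
        ref = np.exp(scores) / np.exp(scores).sum()
        assert np.allclose(alphas, ref, atol=1e-12)
        assert np.isclose(alphas.sum(), 1.0, atol=1e-6)
        assert np.allclose(F, ref @ cands, atol=1e-12)

    def test_wrong_attention_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            fuse_attention(np.zeros(4), None, u=np.zeros(4))


class TestPredictPair:
    def _head(self, dim=8, seed=0):
        rng = np.random.default_rng(seed)
        return (rng.normal(size=(dim // 2, 2 * dim)), rng.normal(size=dim // 2),
                rng.normal(size=dim // 2), 0.0)

    def test_zero_logit_gives_half(self):
        W1, b1, _, _ = self._head()
        assert predict_pair(np.ones(8), np.ones(8), W1, b1, np.zeros(4), 0.0) == 0.5

    def test_output_strictly_inside_unit_interval(self):
        W1, b1, w2, b2 = self._head(seed=3)
        rng = np.random.default_rng(4)
        for _ in range(10):
            p = predict_pair(rng.normal(size=8), rng.normal(size=8), W1, b1, w2, b2)
            assert 0.0 < p < 1.0

    def test_constant_head_ignores_input(self):
        W1, b1, _, _ = self._head(seed=5)
        rng = np.random.default_rng(6)
        b = 1.3
        vals = [predict_pair(rng.normal(size=8), rng.normal(size=8),
                             W1, b1, np.zeros(4), b) for _ in range(5)]
        assert vals == pytest.approx([1 / (1 + np.exp(-b))] * 5)

    def test_dimension_mismatch_rejected(self):
        W1, b1, w2, b2 = self._head()
        with pytest.raises(ValueError, match="FC1"):
            predict_pair(np.ones(9), np.ones(8), W1, b1, w2, b2)


class TestLoss:
    def test_closed_forms(self):
        assert np.isclose(bce_loss([0.5, 0.5], [0, 1]), np.log(2))
        assert bce_loss([0.999999, 0.000001], [1, 0]) < 1e-4

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, 20)
        y = rng.integers(0, 2, 20)
        ref = -np.mean([yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                        for pi, yi in zip(p, y)])
        assert np.isclose(bce_loss(p, y), ref, atol=1e-12)

    def test_saturated_probabilities_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            val = bce_loss([1.0, 0.0], [1, 0])
        assert np.isfinite(val) and val >= 0


@pytest.fixture(scope="module")
def tiny_net(tiny_graph):
    nc = build_node_content(tiny_graph, dim=16, seed=0)
    return HGDTINetwork(tiny_graph, {}, {t: nc.content[t] for t in nc.trainable},
                        dim=16, seed=1)


class TestEncodeContent:
    def test_output_width_matches_dim(self, tiny_net, tiny_graph):
        C = np.random.default_rng(0).random((tiny_graph.n_drugs, 16))
        assert tiny_net.encode_content("drug", C).shape == (tiny_graph.n_drugs, 16)

    def test_deterministic_given_parameters(self, tiny_net):
        C = np.random.default_rng(1).random((3, 16))
        assert np.array_equal(tiny_net.encode_content("drug", C),
                              tiny_net.encode_content("drug", C))

    def test_distinct_type_encoders(self, tiny_net):
        C = np.random.default_rng(2).random((3, 16))
        assert not np.allclose(tiny_net.encode_content("drug", C),
                               tiny_net.encode_content("protein", C))

    def test_wrong_width_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="width"):
            tiny_net.encode_content("drug", np.zeros((2, 8)))


class TestTraining:
    def test_loss_trace_decreases(self, tiny_graph):
        X, y = build_dataset(tiny_graph, ratio=2, threshold=0.1, seed=10)
        clf = HGDTIClassifier(graph=tiny_graph, dim=16, max_epochs=40,
                              batch_size=None, tol=0.0, random_state=10)
        clf.fit(X, y)
        assert clf.loss_trace_[-1] < clf.loss_trace_[0]

    def test_same_seed_is_bitwise_reproducible(self, tiny_graph):
        X, y = build_dataset(tiny_graph, ratio=2, threshold=0.1, seed=4)
        runs = []
        for _ in range(2):
            clf = HGDTIClassifier(graph=tiny_graph, dim=16, max_epochs=5,
                                  random_state=3)
            clf.fit(X, y)
            runs.append((tuple(clf.loss_trace_), clf.network_.param_flat.copy()))
        assert runs[0][0] == runs[1][0]
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_zero_learning_rate_changes_nothing(self, tiny_graph):
        X, y = build_dataset(tiny_graph, ratio=2, threshold=0.1, seed=4)
        clf = HGDTIClassifier(graph=tiny_graph, dim=16, lr=0.0, max_epochs=4,
                              tol=0.0, random_state=3)
        clf.fit(X, y)
        ref = HGDTIClassifier(graph=tiny_graph, dim=16, lr=0.0, max_epochs=1,
                              tol=0.0, random_state=3)
        ref.fit(X, y)
        assert np.array_equal(clf.network_.param_flat, ref.network_.param_flat)
        assert np.allclose(clf.loss_trace_, clf.loss_trace_[0], atol=1e-6)

    def test_single_class_rejected(self, tiny_graph):
        X = np.array([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="class"):
            HGDTIClassifier(graph=tiny_graph, dim=16).fit(X, [1, 1])

    def test_sklearn_clone_and_params_roundtrip(self, tiny_graph):
        from sklearn.base import clone

        clf = HGDTIClassifier(graph=tiny_graph, dim=16, lr=0.01)
        other = clone(clf)
        assert other.get_params()["dim"] == 16
        other.set_params(depth=2)
        assert other.depth == 2


class TestEmbeddings:
    def test_embedding_shapes(self, tiny_graph):
        X, y = build_dataset(tiny_graph, ratio=2, threshold=0.1, seed=0)
        clf = HGDTIClassifier(graph=tiny_graph, dim=16, max_epochs=2, random_state=0)
        clf.fit(X, y)
        emb = clf.embed_all()
        assert emb["drug"].shape == (tiny_graph.n_drugs, 16)
        assert emb["protein"].shape == (tiny_graph.n_proteins, 16)

    def test_isolated_drug_embedding_is_its_content(self, tmp_path):
        from hgdti import load_heterograph

        mats = manual_mats(n_drug=3, n_protein=2)
        mats["drug-interaction-protein"][0, 0] = 1  # drugs 1, 2 stay isolated
        sim = np.eye(3)
        sim[0, 1] = sim[1, 0] = 0.4  # drug 2 has no similarity neighbors either
        mats["drug-similarity-drug"] = sim
        write_dtinet_dir(tmp_path, mats)
        g = load_heterograph(tmp_path)
        nc = build_node_content(g, dim=8, seed=0)
        net = HGDTINetwork(g, dict(nc.content), {}, dim=8, seed=1)
        emb, _ = net.forward_embeddings()
        assert np.allclose(emb["drug"][2], nc.content["drug"][2], atol=1e-6)
        assert not np.allclose(emb["drug"][0], nc.content["drug"][0])

    def test_depth_one_equals_manual_composition(self, tiny_graph):
        nc = build_node_content(tiny_graph, dim=16, seed=2)
        net = HGDTINetwork(tiny_graph, dict(nc.content), {}, dim=16, seed=3)
        emb, cache = net.forward_embeddings()
        f1 = {t: net.encode_content(t, nc.content[t]) for t in net.types}
        u = net.params["attn_u"]
        for v in range(tiny_graph.n_drugs):
            gs = []
            for rel, nbr, Wn, _, has in net.relation_plan["drug"]:
                if has[v]:
                    gs.append(Wn[v] @ f1[nbr])
            F, _ = fuse_attention(nc.content["drug"][v],
                                  np.array(gs) if gs else None, u, slope=0.2)
            assert np.allclose(emb["drug"][v], F, atol=1e-5)

    def test_depth_two_runs_and_differs(self, tiny_graph):
        nc = build_node_content(tiny_graph, dim=16, seed=2)
        one = HGDTINetwork(tiny_graph, dict(nc.content), {}, dim=16, seed=3, depth=1)
        two = HGDTINetwork(tiny_graph, dict(nc.content), {}, dim=16, seed=3, depth=2)
        e1, _ = one.forward_embeddings()
        e2, _ = two.forward_embeddings()
        assert not np.allclose(e1["drug"], e2["drug"])

    def test_permutation_equivariance(self, tiny_dir, tmp_path):
        from hgdti import load_heterograph
        from hgdti.graph import RELATIONS

        g = load_heterograph(tiny_dir)
        rng = np.random.default_rng(8)
        perm = {t: rng.permutation(g.n_nodes(t)) for t in g.nodes}
        mats = {}
        for rel, (src, dst, kind) in RELATIONS.items():
            m = g.relation_matrix(rel)
            if kind == "similarity":
                np.fill_diagonal(m, g.sim_diagonals[rel])
            mats[rel] = m[np.ix_(perm[src], perm[dst])]
        write_dtinet_dir(tmp_path, mats)
        g2 = load_heterograph(tmp_path)

        nc = build_node_content(g, dim=16, seed=5)
        content2 = {t: nc.content[t][perm[t]] for t in g.nodes}
        net = HGDTINetwork(g, dict(nc.content), {}, dim=16, seed=7)
        net2 = HGDTINetwork(g2, content2, {}, dim=16, seed=7)
        net2.param_flat[:] = net.param_flat  # identical weights

        e1, _ = net.forward_embeddings()
        e2, _ = net2.forward_embeddings()
        assert np.allclose(e2["drug"], e1["drug"][perm["drug"]], atol=1e-8)
        X = np.array([[d, t] for d in range(3) for t in range(3)])
        Xp = np.array([[int(np.argsort(perm["drug"])[d]), int(np.argsort(perm["protein"])[t])]
                       for d, t in X])
        assert np.allclose(net.predict_pairs(X), net2.predict_pairs(Xp), atol=1e-8)
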