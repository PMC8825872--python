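import numpy as np
import pytest

from scvgae.graph import CellGraph
from scvgae.interpret import (WeightProducts, attention_vs_latent_distance,
                              learnt_gene_expression, node_attention_overlay,
                              ranked_genes, top_attention_edges,
                              weight_products)
from scvgae.layers import AttentionRecord
from scvgae.model import VGAE


def record(tgt, src, alpha, n_nodes, layer_id=0):
    return AttentionRecord(layer_id=layer_id, tgt=np.asarray(tgt),
                           src=np.asarray(src),
                           alpha=np.atleast_2d(np.asarray(alpha, dtype=float)),
                           n_nodes=n_nodes)


class TestAttentionOverlay:
    def test_mean_of_incoming_coefficients(self):
        rec = record([0, 0], [1, 2], [0.2, 0.4], 3)
        out = node_attention_overlay(rec, "incoming")
        assert out[0] == pytest.approx(0.3)

    def test_isolated_node_self_attention_is_one(self):
        rec = record([0], [0], [1.0], 1)
        assert node_attention_overlay(rec, "incoming")[0] == 1.0

    def test_uniform_attention_gives_equal_overlays(self):
        # 3-clique incl self-loops: every α = 1/3
        tgt, src = np.repeat(np.arange(3), 3), np.tile(np.arange(3), 3)
        rec = record(tgt, src, np.full(9, 1 / 3), 3)
        for direction in ("incoming", "outgoing"):
            np.testing.assert_allclose(node_attention_overlay(rec, direction),
                                       1 / 3)

    def test_head_averaging(self):
        rec = AttentionRecord(layer_id=0, tgt=np.array([0]), src=np.array([0]),
                              alpha=np.array([[0.4], [0.8]]), n_nodes=1)
        assert node_attention_overlay(rec)[0] == pytest.approx(0.6)
        assert node_attention_overlay(rec, head=1)[0] == pytest.approx(0.8)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            node_attention_overlay(record([0], [0], [1.0], 1), "sideways")


class TestTopAttentionEdges:
    def test_full_set_returned_and_ordered(self):
        rec = record([0, 1, 2, 3], [1, 2, 3, 0], [0.1, 0.9, 0.5, 0.3], 4)
        top = top_attention_edges(rec, 4)
        weights = [w for _, _, w in top]
        assert weights == sorted(weights, reverse=True)
        assert top[0][:2] == (1, 2)

    def test_argmax_with_lexicographic_ties(self):
        rec = record([0, 0, 1], [1, 2, 0], [0.5, 0.5, 0.2], 3)
        assert top_attention_edges(rec, 1)[0][:2] == (0, 1)

    def test_exact_top3_on_constructed_record(self):
        rec = record([0, 1, 2, 3, 0], [1, 0, 1, 2, 2],
                     [0.7, 0.9, 0.2, 0.8, 0.4], 4)
        top = top_attention_edges(rec, 3)
        assert [(t, s) for t, s, _ in top] == [(1, 0), (3, 2), (0, 1)]

    def test_n_exceeding_count_warns_and_returns_all(self):
        rec = record([0, 1], [1, 0], [0.5, 0.6], 2)
        with pytest.warns(UserWarning):
            assert len(top_attention_edges(rec, 10)) == 2

    def test_exclude_nodes_filter(self):
        rec = record([0, 1, 2], [1, 2, 0], [0.9, 0.8, 0.7], 3)
        top = top_attention_edges(rec, 3, exclude_nodes=[1])
        assert [(t, s) for t, s, _ in top] == [(2, 0)]

    def test_weight_range_filter(self):
        rec = record([0, 1, 2], [1, 2, 0], [0.9, 0.5, 0.1], 3)
        top = top_attention_edges(rec, 3, weight_range=(0.2, 0.8))
        assert [(t, s) for t, s, _ in top] == [(1, 2)]


class TestAttentionVsLatentDistance:
    def test_identical_latents_give_zero_distance(self):
        rec = record([0], [1], [0.9], 2)
        Z = np.ones((2, 3))
        assert attention_vs_latent_distance(rec, Z, 1)[0][2] == 0.0

    def test_orthonormal_vectors_distance_sqrt2(self):
        rec = record([0], [1], [0.9], 2)
        Z = np.eye(2)
        assert attention_vs_latent_distance(rec, Z, 1)[0][2] == \
            pytest.approx(np.sqrt(2))

    def test_ranks_follow_attention_order(self):
        rec = record([0, 1, 2], [1, 2, 0], [0.3, 0.9, 0.6], 3)
        Z = np.diag([1.0, 2.0, 3.0])
        out = attention_vs_latent_distance(rec, Z, 3)
        assert [r for r, _, _ in out] == [0, 1, 2]
        assert [a for _, a, _ in out] == [0.9, 0.6, 0.3]
        assert out[0][2] == pytest.approx(np.sqrt(4 + 9))  # pair (1,2)


class TestWeightProducts:
    def test_identity_chain(self):
        wp = weight_products([np.eye(3)], np.eye(3), np.eye(3))
        np.testing.assert_allclose(wp.P_mu, np.eye(3))

    def test_scalar_chain(self):
        wp = weight_products([2 * np.eye(3), 3 * np.eye(3)], np.eye(3),
                             np.eye(3))
        np.testing.assert_allclose(wp.P_mu, 6 * np.eye(3))

    def test_random_chain_matches_triple_product(self):
        rng = np.random.default_rng(0)
        W1 = rng.standard_normal((4, 3))   # (K·D1) × D
        W2 = rng.standard_normal((4, 4))   # (K·D2) × (K·D1)
        Wm = rng.standard_normal((2, 4))   # L × (K·D2)
        Ws = rng.standard_normal((2, 4))
        wp = weight_products([W1, W2], Wm, Ws)
        np.testing.assert_allclose(wp.P_mu, W1.T @ W2.T @ Wm.T, atol=1e-12)
        np.testing.assert_allclose(wp.P_sigma, W1.T @ W2.T @ Ws.T, atol=1e-12)
        assert wp.P_mu.shape == (3, 2)

    def test_equals_jacobian_of_linear_encoder_path(self):
        """With attention frozen to self-loops and activations removed the
        encoder is linear; its Jacobian must equal the weight product."""
        model = VGAE(d_in=4, inner_dims=(3,), latent_dim=2, n_heads=2, seed=1)
        w = model.stacked_weights()
        wp = weight_products(w["inner"], w["mu"], w["sigma"])

        def linear_mu(x):
            h = x @ w["inner"][0].T
            return h @ w["mu"].T

        probe = np.zeros(4)
        jac = np.empty((4, 2))
        h = 1e-7
        for d in range(4):
            e = np.zeros(4)
            e[d] = h
            jac[d] = (linear_mu(e) - linear_mu(-e)) / (2 * h)
        np.testing.assert_allclose(wp.P_mu, jac, atol=1e-6)

    def test_chain_mismatch_rejected(self):
        with pytest.raises(ValueError):
            WeightProducts(P_mu=np.ones((2, 2)), P_sigma=np.ones((3, 2)))


class TestRankedGenes:
    def test_single_dimension_sorted_by_weight(self):
        wp = WeightProducts(P_mu=np.array([[3.0], [1.0], [2.0]]),
                            P_sigma=np.zeros((3, 1)))
        E = np.ones((4, 1))
        rep = ranked_genes(wp, E, np.zeros(4, dtype=int), top_per_dim=2)
        assert [g for g, _ in rep.appearance[0]] == [0, 2]

    def test_dominant_gene_saturates_appearance_count(self):
        L = 3
        P = np.ones((5, L)) * 0.1
        P[2] = 10.0  # gene 2 tops every latent dimension
        wp = WeightProducts(P_mu=P, P_sigma=np.zeros_like(P))
        E = np.random.default_rng(0).random((6, L))
        rep = ranked_genes(wp, E, np.zeros(6, dtype=int), top_per_dim=1)
        assert rep.appearance[0][0] == (2, L)

    def test_matches_enumeration_oracle(self):
        """5-gene, 2-dim, 2-cluster case against exhaustive hand ranking."""
        rng = np.random.default_rng(4)
        P = rng.standard_normal((5, 2))
        E = rng.standard_normal((8, 2))
        labels = np.repeat([0, 1], 4)
        rep = ranked_genes(WeightProducts(P_mu=P, P_sigma=P * 0), E, labels,
                           top_per_dim=2, top_weight_pool=4)
        for c in (0, 1):
            counts = {}
            for d in range(2):
                for g in sorted(range(5),
                                key=lambda g: (-abs(P[g, d]), g))[:2]:
                    counts[g] = counts.get(g, 0) + 1
            expected = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            assert rep.appearance[c] == expected

    def test_invariant_to_cell_order_and_label_names(self):
        rng = np.random.default_rng(5)
        P = rng.standard_normal((6, 3))
        E = rng.standard_normal((10, 3))
        labels = np.array([0] * 5 + [1] * 5)
        wp = WeightProducts(P_mu=P, P_sigma=P * 0)
        rep = ranked_genes(wp, E, labels)
        perm = rng.permutation(10)
        rep_p = ranked_genes(wp, E[perm], labels[perm])
        assert rep.appearance == rep_p.appearance
        swapped = ranked_genes(wp, E, 1 - labels)
        assert swapped.appearance[1] == rep.appearance[0]

    def test_label_embedding_mismatch_rejected(self):
        wp = WeightProducts(P_mu=np.ones((3, 2)), P_sigma=np.ones((3, 2)))
        with pytest.raises(ValueError):
            ranked_genes(wp, np.ones((4, 2)), np.zeros(3, dtype=int))


class TestLearntExpression:
    def test_identity_embedding_returns_loading(self):
        P = np.array([[1.0, 2.0], [3.0, 4.0]])
        wp = WeightProducts(P_mu=P, P_sigma=P * 0)
        out = learnt_gene_expression(np.eye(2), wp, 1)
        np.testing.assert_allclose(out, P[1])

    def test_zero_loading_gives_zeros(self):
        wp = WeightProducts(P_mu=np.zeros((2, 3)), P_sigma=np.zeros((2, 3)))
        np.testing.assert_allclose(
            learnt_gene_expression(np.random.default_rng(0).random((5, 3)),
                                   wp, 0), 0)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(6)
        E = rng.standard_normal((4, 3))
        P = rng.standard_normal((5, 3))
        wp = WeightProducts(P_mu=P, P_sigma=P * 0)
        for g in range(5):
            expected = [E[i] @ P[g] for i in range(4)]
            np.testing.assert_allclose(learnt_gene_expression(E, wp, g),
                                       expected)

    def test_out_of_range_gene(self):
        wp = WeightProducts(P_mu=np.ones((2, 2)), P_sigma=np.ones((2, 2)))
        with pytest.raises(IndexError):
            learnt_gene_expression(np.ones((3, 2)), wp, 5)


class TestEndToEndWeightExtraction:
    def test_stacked_weights_compose_with_trained_model(self, six_node_graph):
        model = VGAE(d_in=5, inner_dims=(3, 2), latent_dim=2, n_heads=2, seed=3)
        w = model.stacked_weights()
        assert w["inner"][0].shape == (6, 5)    # K·D1 × D
        assert w["inner"][1].shape == (4, 6)    # K·D2 × K·D1
        assert w["mu"].shape == (2, 4)          # L × K·D2
        wp = weight_products(w["inner"], w["mu"], w["sigma"])
        assert wp.P_mu.shape == (5, 2)
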