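import numpy as np
import pytest

from scvgae.autodiff import Tensor
from scvgae.graph import CellGraph
from scvgae.layers import GATLayer
from scvgae.model import (VGAE, EncoderOutput, decode_edge_prob,
                          feature_recon_loss, kl_loss, mmd_loss, recon_loss,
                          reparameterize, total_loss)
from scvgae.train import sample_negative_edges


def enc(mu, log_sigma):
    return EncoderOutput(mu=Tensor(np.atleast_2d(mu)),
                         log_sigma=Tensor(np.atleast_2d(log_sigma)))


class TestEncoder:
    def test_output_shapes_reduce_dimension(self, six_node_graph):
        model = VGAE(d_in=10, inner_dims=(4, 4), latent_dim=3, n_heads=2)
        rng = np.random.default_rng(0)
        out, records = model.encode(rng.random((6, 10)), six_node_graph)
        assert out.mu.shape == (6, 3) and out.log_sigma.shape == (6, 3)
        assert len(records) == 4  # 2 inner + mu + sigma

    def test_composition_matches_manual_layers(self, six_node_graph):
        """encode() with one inner layer equals hand-composed GAT calls."""
        model = VGAE(d_in=3, inner_dims=(2,), latent_dim=2, n_heads=1, seed=5)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 3))
        out, _ = model.encode(X, six_node_graph)
        h1, _ = model.inner_layers[0](Tensor(X), six_node_graph)
        mu, _ = model.mu_layer(h1.relu(), six_node_graph)
        ls, _ = model.logsigma_layer(h1.relu(), six_node_graph)
        np.testing.assert_allclose(out.mu.detach(), mu.detach(), atol=1e-12)
        np.testing.assert_allclose(out.log_sigma.detach(), ls.detach(), atol=1e-12)

    def test_zero_input_zero_bias_gives_zero_posterior(self, six_node_graph):
        model = VGAE(d_in=4, inner_dims=(3,), latent_dim=2, n_heads=2)
        out, _ = model.encode(np.zeros((6, 4)), six_node_graph)
        np.testing.assert_allclose(out.mu.detach(), 0, atol=1e-12)
        np.testing.assert_allclose(out.log_sigma.detach(), 0, atol=1e-12)

    def test_width_mismatch_raises_at_construction(self):
        model = VGAE(d_in=4, inner_dims=(3,), latent_dim=2)
        g = CellGraph(2, np.array([[0, 1]]))
        with pytest.raises(ValueError):
            model.encode(np.ones((2, 5)), g)


class TestReparameterize:
    def test_forced_zero_noise_returns_mu(self):
        e = enc([[1.0, 2.0]], [[0.3, -0.2]])
        z = reparameterize(e, eps=np.zeros((1, 2)))
        np.testing.assert_allclose(z.Z.detach(), [[1.0, 2.0]])

    def test_vanishing_sigma_limit(self):
        e = enc([[1.0, 2.0]], [[-20.0, -20.0]])
        z = reparameterize(e, seed=0)
        np.testing.assert_allclose(z.Z.detach(), [[1.0, 2.0]], atol=1e-6)

    def test_monte_carlo_mean(self):
        n = 10 ** 5
        e = EncoderOutput(mu=Tensor(np.full((n, 1), 5.0)),
                          log_sigma=Tensor(np.zeros((n, 1))))
        z = reparameterize(e, seed=123)
        assert abs(z.Z.detach().mean() - 5.0) < 0.02

    def test_seed_determinism(self):
        e = enc([[0.0, 0.0]], [[0.0, 0.0]])
        a = reparameterize(e, seed=7).Z.detach()
        b = reparameterize(e, seed=7).Z.detach()
        np.testing.assert_array_equal(a, b)


class TestDecoder:
    def test_zero_vectors_give_half(self):
        assert decode_edge_prob(np.zeros(3), np.zeros(3)).detach() == 0.5

    def test_closed_form_sigmoid(self):
        p = decode_edge_prob(np.array([2.0]), np.array([2.0])).detach()
        assert p == pytest.approx(1 / (1 + np.exp(-4)), abs=1e-6)
        assert p == pytest.approx(0.9820, abs=1e-4)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.standard_normal((2, 4))
            assert decode_edge_prob(a, b).detach() == \
                pytest.approx(decode_edge_prob(b, a).detach())

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            decode_edge_prob(np.zeros(2), np.zeros(3))


class TestLosses:
    def test_kl_zero_at_prior(self):
        assert kl_loss(enc([[0.0]], [[0.0]])).detach() == 0.0

    def test_kl_unit_mean(self):
        assert kl_loss(enc([[1.0]], [[0.0]])).detach() == pytest.approx(0.5)

    def test_kl_sigma_squared_e(self):
        # sigma^2 = e → 0.5(e − 1 − 1)
        val = kl_loss(enc([[0.0]], [[0.5]])).detach()
        assert val == pytest.approx(0.5 * (np.e - 2), abs=1e-10)
        assert val == pytest.approx(0.3591, abs=1e-4)

    def test_kl_zero_iff_standard_normal(self):
        rng = np.random.default_rng(0)
        e = enc(rng.standard_normal((3, 2)) * 0.1, rng.standard_normal((3, 2)) * 0.1)
        assert kl_loss(e).detach() > 0

    def test_recon_chance_level_is_log2(self):
        z = np.zeros((3, 2))  # all probabilities 0.5
        val = recon_loss(z, [[0, 1]], [[0, 2]]).detach()
        assert val == pytest.approx(np.log(2), abs=1e-12)

    def test_recon_perfect_predictions_vanish(self):
        z = np.array([[10.0], [10.0], [-10.0]])
        val = recon_loss(z, [[0, 1]], [[0, 2]]).detach()
        assert val < 1e-6

    def test_recon_single_pos_inverse_e(self):
        # choose z so that sigmoid(z_0 · z_1) = e^{-1}
        c = np.log((1 / np.e) / (1 - 1 / np.e))
        z = np.array([[1.0], [c]])
        assert recon_loss(z, [[0, 1]], np.empty((0, 2))).detach() == \
            pytest.approx(1.0, abs=1e-10)

    def test_recon_requires_positives(self):
        with pytest.raises(ValueError):
            recon_loss(np.zeros((2, 1)), np.empty((0, 2)), [[0, 1]])

    def test_recon_monotone_in_predictions(self):
        """Loss falls as positives score higher and negatives lower."""
        scale = np.linspace(0.1, 2.0, 8)
        losses = []
        for s in scale:
            z = np.array([[s], [s], [-s]])
            losses.append(float(recon_loss(z, [[0, 1]], [[0, 2]]).detach()))
        assert np.all(np.diff(losses) < 0)

    def test_mmd_identical_samples_zero(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((10, 3))
        assert mmd_loss(z, z.copy()).detach() == pytest.approx(0.0, abs=1e-12)

    def test_mmd_two_singletons_closed_form(self):
        z, zp, bw = np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]), 2.0
        expected = 2 - 2 * np.exp(-2.0 / (2 * bw))
        assert mmd_loss(z, zp, kernel_bandwidth=bw).detach() == \
            pytest.approx(expected, abs=1e-12)

    def test_mmd_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.standard_normal((8, 2))
            b = rng.standard_normal((12, 2)) + rng.normal()
            assert mmd_loss(a, b).detach() >= -1e-12

    def test_feature_recon_exact_zero_and_mse(self):
        X = np.ones((3, 2))
        exact = feature_recon_loss(np.ones((3, 1)), X, lambda z: Tensor(X))
        assert exact.detach() == 0.0
        zeros = feature_recon_loss(np.ones((3, 1)), X,
                                   lambda z: Tensor(np.zeros((3, 2))))
        assert zeros.detach() == pytest.approx(1.0)

    def test_feature_recon_scalar_case(self):
        val = feature_recon_loss(np.zeros((1, 1)), np.array([[1.0]]),
                                 lambda z: z + 0.5).detach()
        assert val == pytest.approx(0.25)

    def test_total_loss_additivity(self):
        reg, rec, feat = Tensor(0.5), Tensor(np.log(2)), Tensor(0.1)
        assert total_loss(Tensor(0.0), Tensor(0.0)).detach() == 0.0
        assert total_loss(reg, rec).detach() == pytest.approx(0.5 + np.log(2))
        with_feat = total_loss(reg, rec, feat, use_feature_recon=True).detach()
        assert with_feat == pytest.approx(0.5 + np.log(2) + 0.1)

    def test_total_loss_unknown_reg_kind(self):
        with pytest.raises(ValueError):
            total_loss(Tensor(0.0), Tensor(0.0), reg_kind="l2")

    def test_loss_finite_under_extreme_parameters(self, six_node_graph):
        model = VGAE(d_in=3, inner_dims=(2,), latent_dim=2, seed=0)
        for p in model.parameters():
            p.data *= 100.0
        out, _ = model.encode(np.random.default_rng(0).random((6, 3)) * 50,
                              six_node_graph)
        z = reparameterize(out, seed=0)
        neg = sample_negative_edges(six_node_graph, 3, seed=0)
        val = total_loss(kl_loss(out),
                         recon_loss(z, six_node_graph.edges, neg)).detach()
        assert np.isfinite(val)


class TestGradients:
    def test_finite_difference_gradient_check(self, six_node_graph):
        """Autodiff gradients of the full loss match central differences."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 4))
        model = VGAE(d_in=4, inner_dims=(3,), latent_dim=2, n_heads=2, seed=7)
        eps = rng.standard_normal((6, 2))
        neg = sample_negative_edges(six_node_graph, six_node_graph.n_edges,
                                    seed=1)

        def loss_value():
            out, _ = model.encode(X, six_node_graph)
            z = reparameterize(out, eps=eps)
            return total_loss(kl_loss(out),
                              recon_loss(z, six_node_graph.edges, neg))

        loss = loss_value()
        loss.backward()
        h = 1e-6
        for p in model.parameters():
            flat, gflat = p.data.ravel(), p.grad.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 4)):
                old = flat[idx]
                flat[idx] = old + h
                lp = loss_value().detach()
                flat[idx] = old - h
                lm = loss_value().detach()
                flat[idx] = old
                assert (lp - lm) / (2 * h) == pytest.approx(gflat[idx], abs=1e-4)


class TestCheckpoint:
    def test_save_load_round_trip(self, six_node_graph, tmp_path):
        """A reloaded checkpoint reproduces the encoder outputs exactly."""
        rng = np.random.default_rng(0)
        X = rng.random((6, 4))
        model = VGAE(d_in=4, inner_dims=(3,), latent_dim=2, n_heads=2, seed=2)
        path = tmp_path / "model.npz"
        model.save(path)
        clone = VGAE.load(path)
        a, _ = model.encode(X, six_node_graph)
        b, _ = clone.encode(X, six_node_graph)
        np.testing.assert_array_equal(a.mu.detach(), b.mu.detach())
        np.testing.assert_array_equal(a.log_sigma.detach(), b.log_sigma.detach())
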