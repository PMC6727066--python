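import numpy as np
import pytest

from gclmi.graph import convolved_features
from gclmi.model import (
    Embeddings,
    ModelParams,
    TrainingMasks,
    compute_loss,
    decode,
    encode,
    init_params,
    loss_gradients,
    predict_scores,
    sample_negatives,
    train,
)


class TestInit:
    def test_same_seed_bit_identical(self):
        a, b = init_params(24, 8, 5), init_params(24, 8, 5)
        np.testing.assert_array_equal(a.W_e, b.W_e)
        np.testing.assert_array_equal(a.W_d, b.W_d)

    def test_different_seeds_differ(self):
        a, b = init_params(24, 8, 5), init_params(24, 8, 6)
        assert not np.array_equal(a.W_e, b.W_e)

    def test_shapes_and_zero_bias(self):
        p = init_params(24, 8, 0)
        assert p.W_e.shape == (24, 8)
        assert p.W_d.shape == (8, 8)
        np.testing.assert_array_equal(p.B_e, np.zeros(8))


class TestEncodeDecode:
    def test_zero_weights_give_zero_embeddings(self):
        p = ModelParams(np.zeros((3, 2)), np.zeros(2), np.zeros((2, 2)))
        emb = encode(np.random.default_rng(0).random((4, 3)), p, n_lnc=2)
        np.testing.assert_array_equal(emb.E, 0)

    def test_relu_clamps_negative_preactivations(self):
        p = ModelParams(np.array([[-1.0, 2.0]]), np.zeros(2), np.eye(2))
        emb = encode(np.array([[1.0]]), p, n_lnc=1)
        np.testing.assert_array_equal(emb.E, [[0.0, 2.0]])

    def test_hand_computed_encoding(self):
        p = ModelParams(np.array([[1.0], [1.0]]), np.array([0.5]), np.eye(1))
        emb = encode(np.array([[1.0, 2.0]]), p, n_lnc=1)
        np.testing.assert_allclose(emb.E, [[3.5]])

    def test_orthogonal_factors_decode_to_zero(self):
        emb = Embeddings(E=np.array([[1.0, 0], [0, 1]]), n_lnc=1)
        np.testing.assert_allclose(decode(emb, np.eye(2)), [[0.0]])

    def test_decoder_weight_couples_factors(self):
        emb = Embeddings(E=np.array([[1.0, 0], [0, 1]]), n_lnc=1)
        W_d = np.array([[0.0, 1], [0, 0]])
        np.testing.assert_allclose(decode(emb, W_d), [[1.0]])

    @pytest.mark.parametrize("seed", range(4))
    def test_decode_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_l, n_m, k = rng.integers(1, 10), rng.integers(1, 10), rng.integers(1, 6)
        E = rng.normal(size=(n_l + n_m, k))
        W_d = rng.normal(size=(k, k))
        emb = Embeddings(E=E, n_lnc=n_l)
        M = decode(emb, W_d)
        E_l, E_m = E[:n_l], E[n_l:]
        oracle = np.zeros((n_l, n_m))
        for i in range(n_l):
            for j in range(n_m):
                oracle[i, j] = sum(
                    E_l[i, a] * W_d[a, b] * E_m[j, b]
                    for a in range(k) for b in range(k)
                )
        np.testing.assert_allclose(M, oracle, atol=1e-10)

    def test_embeddings_nonnegative(self):
        rng = np.random.default_rng(3)
        p = init_params(5, 4, 0)
        emb = encode(rng.normal(size=(7, 5)), p, n_lnc=4)
        assert (emb.E >= 0).all()


class TestNegativeSampling:
    def test_p_zero_gives_empty_mask(self):
        M = np.eye(4)
        omega = sample_negatives(M, 0.0, np.random.default_rng(0))
        assert omega.sum() == 0

    def test_exact_count_at_ratio_three(self):
        rng = np.random.default_rng(1)
        M = np.zeros((8, 8))
        M.flat[rng.choice(64, 8, replace=False)] = 1.0
        omega = sample_negatives(M, 3.0, rng)
        assert omega.sum() == 24
        assert (omega * M).sum() == 0  # only zero entries sampled

    def test_capped_when_few_zeros(self, caplog):
        M = np.ones((3, 3))
        M[0, 0] = M[1, 1] = 0.0
        with caplog.at_level("WARNING", logger="gclmi"):
            omega = sample_negatives(M, 10.0, np.random.default_rng(0))
        assert omega.sum() == 2
        assert any("capping" in r.message for r in caplog.records)


class TestLoss:
    def make_masks(self, omega_p, omega_n):
        return TrainingMasks(np.asarray(omega_p, float), np.asarray(omega_n, float), 1.0)

    def test_perfect_fit_zero_params_zero_loss(self):
        p = ModelParams(np.zeros((2, 1)), np.zeros(1), np.zeros((1, 1)))
        masks = self.make_masks([[1.0]], [[0.0]])
        loss, err = compute_loss(np.array([[1.0]]), np.array([[1.0]]), masks, p, lam=1.0)
        assert loss == 0.0 and err == 0.0

    def test_single_unit_residual(self):
        p = ModelParams(np.zeros((2, 1)), np.zeros(1), np.zeros((1, 1)))
        masks = self.make_masks([[1.0]], [[0.0]])
        loss, err = compute_loss(np.array([[0.0]]), np.array([[1.0]]), masks, p, lam=0.0)
        assert loss == 1.0 and err == 1.0

    def test_mean_of_two_residuals(self):
        p = ModelParams(np.zeros((2, 1)), np.zeros(1), np.zeros((1, 1)))
        masks = self.make_masks([[1.0, 0.0]], [[0.0, 1.0]])
        M_pred = np.array([[0.0, 0.0]])
        M = np.array([[1.0, 0.0]])
        loss, err = compute_loss(M_pred, M, masks, p, lam=0.0)
        assert loss == 0.5

    def test_empty_mask_is_error(self):
        p = ModelParams(np.zeros((2, 1)), np.zeros(1), np.zeros((1, 1)))
        masks = self.make_masks([[0.0]], [[0.0]])
        with pytest.raises(ValueError, match="empty"):
            compute_loss(np.zeros((1, 1)), np.zeros((1, 1)), masks, p)

    def test_disjoint_mask_invariant_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            TrainingMasks(np.ones((2, 2)), np.ones((2, 2)), 1.0)

    def test_loss_invariant_under_node_permutation(self):
        rng = np.random.default_rng(4)
        n_l, n_m, d, k = 5, 4, 3, 2
        G = rng.normal(size=(n_l + n_m, d))
        params = init_params(d, k, 0)
        params.B_e = rng.normal(size=k)  # nonzero bias for a stricter check
        M = (rng.random((n_l, n_m)) < 0.5).astype(float)
        omega_p = (M > 0).astype(float)
        omega_n = sample_negatives(M, 1.0, rng)
        masks = TrainingMasks(omega_p, omega_n, 1.0)
        loss0, _, _ = loss_gradients(G, M, masks, params, lam=0.7)
        # permute lncRNA and miRNA labels consistently
        pl, pm = rng.permutation(n_l), rng.permutation(n_m)
        node_perm = np.concatenate([pl, n_l + pm])
        masks_p = TrainingMasks(omega_p[np.ix_(pl, pm)], omega_n[np.ix_(pl, pm)], 1.0)
        loss1, _, _ = loss_gradients(G[node_perm], M[np.ix_(pl, pm)], masks_p, params, lam=0.7)
        np.testing.assert_allclose(loss0, loss1, rtol=1e-12)


class TestGradients:
    def test_matches_finite_differences_on_toy(self):
        """Analytic gradients of the masked loss agree with central
        differences on a 4x3 problem within 1e-4 relative error."""
        rng = np.random.default_rng(11)
        n_l, n_m, d, k = 4, 3, 5, 2
        G = rng.normal(size=(n_l + n_m, d))
        params = init_params(d, k, 1)
        params.B_e = 0.3 * rng.normal(size=k)  # move off the ReLU kink
        M = (rng.random((n_l, n_m)) < 0.5).astype(float)
        omega_p = (M > 0).astype(float)
        omega_n = sample_negatives(M, 1.0, rng)
        masks = TrainingMasks(omega_p, omega_n, 1.0)
        lam = 0.5

        _, _, grads = loss_gradients(G, M, masks, params, lam=lam)

        eps = 1e-6
        for name in ("W_e", "B_e", "W_d"):
            arr = getattr(params, name)
            analytic = getattr(grads, name)
            numeric = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _, _ = loss_gradients(G, M, masks, params, lam=lam)
                arr[idx] = orig - eps
                lm, _, _ = loss_gradients(G, M, masks, params, lam=lam)
                arr[idx] = orig
                numeric[idx] = (lp - lm) / (2 * eps)
            denom = np.maximum(np.abs(numeric), 1e-8)
            rel = np.abs(analytic - numeric) / denom
            assert rel.max() < 1e-4, f"{name}: max rel err {rel.max():.2e}"

    def test_stronger_regularization_shrinks_weights(self, tiny_dataset):
        # short horizon: with long training every lambda in this range
        # collapses the tiny problem's weights to ~0 and the ordering drowns
        # in noise
        norms = []
        for lam in (0.001, 0.1, 10.0):
            m = train(tiny_dataset, n_latent=3, lam=lam, epochs=50, lr=0.01, seed=0)
            norms.append(np.linalg.norm(m.params.W_e))
        assert norms[0] > norms[1] > norms[2]


class TestTraining:
    def test_loss_decreases(self, tiny_dataset):
        m = train(tiny_dataset, n_latent=3, epochs=200, seed=0)
        assert m.loss_history[-1] < m.loss_history[0]
        assert len(m.loss_history) == len(m.error_history) == 200

    def test_same_seed_identical_histories(self, tiny_dataset):
        m1 = train(tiny_dataset, n_latent=3, epochs=50, seed=7)
        m2 = train(tiny_dataset, n_latent=3, epochs=50, seed=7)
        assert m1.loss_history == m2.loss_history
        np.testing.assert_array_equal(m1.params.W_e, m2.params.W_e)

    def test_zero_weight_model_scores_zero(self, tiny_dataset):
        m = train(tiny_dataset, n_latent=3, epochs=1, seed=0)
        m.params.W_e[:] = 0
        m.params.B_e[:] = 0
        m.params.W_d[:] = 0
        np.testing.assert_array_equal(predict_scores(m, tiny_dataset), 0)

    def test_scores_cover_every_pair(self, tiny_dataset):
        m = train(tiny_dataset, n_latent=3, epochs=30, seed=0)
        scores = predict_scores(m, tiny_dataset)
        assert scores.shape == tiny_dataset.shape
        assert np.isfinite(scores).all()

    def test_heldout_positives_outscore_random_negatives(self, benchmark_dataset):
        """After training with one fifth of the edges hidden, held-out true
        pairs score higher on average than never-interacting pairs."""
        rng = np.random.default_rng(0)
        M = benchmark_dataset.M
        pos = np.argwhere(M > 0)
        hide = pos[rng.choice(len(pos), len(pos) // 5, replace=False)]
        M_train = M.copy()
        M_train[hide[:, 0], hide[:, 1]] = 0.0
        ds = benchmark_dataset.with_interactions(M_train)
        m = train(ds, seed=0)
        scores = predict_scores(m, ds)
        held_mean = scores[hide[:, 0], hide[:, 1]].mean()
        neg = np.argwhere(M == 0)
        neg = neg[rng.choice(len(neg), len(hide), replace=False)]
        neg_mean = scores[neg[:, 0], neg[:, 1]].mean()
        assert held_mean > neg_mean
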