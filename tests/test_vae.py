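import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import logsumexp

from pairdistill import random_independent_model
from pairdistill.vae import SequenceVAE, _one_hot


def zero_param_vae(N=4, q=3, hidden=6, latent=2):
    shapes = {
        "W_enc": (hidden, N * q), "b_enc": (hidden,),
        "W_mu": (latent, hidden), "b_mu": (latent,),
        "W_sigma": (latent, hidden), "b_sigma": (latent,),
        "W_dec": (hidden, latent), "b_dec": (hidden,),
        "W_s": (N * q, hidden), "b_s": (N * q,),
    }
    return SequenceVAE.from_parameters(
        {k: np.zeros(s) for k, s in shapes.items()}, N=N, q=q
    )


class TestEncodeDecode:
    def test_zero_parameters_give_prior_and_uniform(self):
        m = zero_param_vae()
        mu, lv = m.encode(np.zeros((2, 4), dtype=int))
        assert np.all(mu == 0) and np.all(lv == 0)
        probs = m.decode(np.zeros((1, 2)))
        assert np.allclose(probs, 1 / 3)

    def test_bias_shift_moves_mu_only(self, small_vae):
        codes = np.array([[0, 1, 2, 0, 1]])
        mu1, lv1 = small_vae.encode(codes)
        shifted = SequenceVAE.from_parameters(
            {**small_vae.params_, "b_mu": small_vae.params_["b_mu"] + 2.5},
            N=5, q=3,
        )
        mu2, lv2 = shifted.encode(codes)
        assert np.allclose(mu2 - mu1, 2.5)
        assert np.allclose(lv1, lv2)

    def test_tanh_saturation_bounds_mu(self, small_vae):
        big = SequenceVAE.from_parameters(
            {**small_vae.params_, "W_enc": small_vae.params_["W_enc"] * 1e3},
            N=5, q=3,
        )
        mu, _ = big.encode(np.array([[0, 1, 2, 0, 1]]))
        bound = np.abs(big.params_["W_mu"]).sum(axis=1) + np.abs(big.params_["b_mu"])
        assert np.all(np.abs(mu[0]) <= bound + 1e-9)

    def test_decode_rows_sum_to_one(self, small_vae, rng):
        z = rng.normal(size=(50, 2))
        probs = small_vae.decode(z)
        assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-12)

    def test_decoder_ignores_z_when_wdec_zero(self, small_vae, rng):
        m = SequenceVAE.from_parameters(
            {**small_vae.params_, "W_dec": np.zeros_like(small_vae.params_["W_dec"])},
            N=5, q=3,
        )
        p1 = m.decode(rng.normal(size=(1, 2)))
        p2 = m.decode(rng.normal(size=(1, 2)))
        assert np.allclose(p1, p2)


class TestElbo:
    def test_decoder_at_prior_elbo_is_factorized_loglik(self, rng):
        m = zero_param_vae()
        bs = rng.normal(size=12)
        m.params_["b_s"] = bs
        codes = rng.integers(0, 3, size=(6, 4))
        elbo = m.elbo(codes, n_mc=3, seed=0)
        logits = bs.reshape(4, 3)
        lp = logits - logsumexp(logits, axis=1, keepdims=True)
        expected = lp[np.arange(4)[None, :], codes].sum(axis=1)
        assert np.allclose(elbo, expected)

    def test_kl_term_nonnegative(self, small_vae, rng):
        codes = rng.integers(0, 3, size=(10, 5))
        mu, lv = small_vae.encode(codes)
        kl = 0.5 * np.sum(np.exp(lv) + mu**2 - 1.0 - lv, axis=1)
        assert np.all(kl >= 0)

    def test_elbo_below_importance_sampling_estimate(self, small_vae, rng):
        # Jensen: ELBO <= log p(s); compare against a high-K IS estimate
        codes = rng.integers(0, 3, size=(20, 5))
        elbo = small_vae.elbo(codes, n_mc=20, seed=1)
        ll = -small_vae.energy_importance(codes, K=4000, seed=2)
        assert np.all(elbo <= ll + 0.05)

    def test_deterministic_given_seed(self, small_vae, rng):
        codes = rng.integers(0, 3, size=(4, 5))
        assert np.allclose(
            small_vae.elbo(codes, n_mc=2, seed=9), small_vae.elbo(codes, n_mc=2, seed=9)
        )


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        truth = random_independent_model(4, 3, seed=1)
        aln = truth.sample(25, seed=2)
        vae = SequenceVAE(hidden=5, latent=2, weight_decay=0.01, steps=1, seed=3, n_mc=2)
        vae.fit(aln)
        X = _one_hot(aln.codes, 3)
        w = np.full(len(aln), 1 / len(aln))
        p0 = {k: v.copy() for k, v in vae.params_.items()}

        def loss(params):
            vae.params_ = params
            return vae._loss_and_grads(X, aln.codes, w, np.random.default_rng(42))

        _, g = loss({k: v.copy() for k, v in p0.items()})
        rng = np.random.default_rng(0)
        for key in p0:
            flat_idx = rng.choice(p0[key].size, size=min(3, p0[key].size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p0[key].shape)
                eps = 1e-6
                pp = {k: v.copy() for k, v in p0.items()}
                pp[key][idx] += eps
                lp, _ = loss(pp)
                pm = {k: v.copy() for k, v in p0.items()}
                pm[key][idx] -= eps
                lm, _ = loss(pm)
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[key][idx]) < 1e-6 * max(1.0, abs(num))


class TestTraining:
    def test_loss_decreases_over_first_100_steps(self):
        truth = random_independent_model(6, 3, seed=4)
        aln = truth.sample(300, seed=5)
        vae = SequenceVAE(hidden=10, latent=2, weight_decay=0.001, steps=100,
                          lr=0.05, seed=6).fit(aln)
        first = np.mean(vae.loss_history_[:5])
        last = np.mean(vae.loss_history_[-5:])
        assert last < first

    def test_recovers_profile_marginals_at_prior_center(self):
        truth = random_independent_model(10, 4, seed=7)
        aln = truth.sample(2000, seed=8)
        vae = SequenceVAE(hidden=16, latent=3, weight_decay=0.001, steps=800,
                          lr=0.1, seed=9).fit(aln)
        probs = vae.decode(np.zeros((1, 3)))[0]
        target = truth.site_probabilities()
        tv = 0.5 * np.abs(probs - target).sum(axis=1)
        assert np.all(tv < 0.05)

    def test_huge_weight_decay_forces_uniform_decoder(self):
        truth = random_independent_model(5, 3, seed=10)
        aln = truth.sample(200, seed=11)
        vae = SequenceVAE(hidden=6, latent=2, weight_decay=5.0, steps=300,
                          lr=0.05, seed=12).fit(aln)
        # decay drives the weight matrices (not biases) toward zero, so the
        # decoder output loses all z dependence
        assert np.max(np.abs(vae.params_["W_s"])) < 1e-2
        p1 = vae.decode(np.full((1, 2), 3.0))[0]
        p2 = vae.decode(np.full((1, 2), -3.0))[0]
        assert np.max(np.abs(p1 - p2)) < 1e-3

    def test_weight_decay_monotonically_shrinks_weights(self):
        truth = random_independent_model(5, 3, seed=13)
        aln = truth.sample(300, seed=14)
        norms = []
        for wd in [0.1, 0.05, 0.01, 0.005, 0.001]:
            vae = SequenceVAE(hidden=6, latent=2, weight_decay=wd, steps=200,
                              lr=0.05, seed=15).fit(aln)
            norms.append(sum(np.sum(vae.params_[k] ** 2)
                             for k in ("W_enc", "W_mu", "W_sigma", "W_dec", "W_s")))
        assert all(a <= b + 1e-9 for a, b in zip(norms, norms[1:]))


class TestSampling:
    def test_zero_model_uniform_positions(self):
        m = zero_param_vae(N=5, q=4, hidden=6, latent=2)
        s = m.sample(100_000, seed=0)
        freqs = np.stack([np.bincount(s.codes[:, i], minlength=4) for i in range(5)]) / 1e5
        assert np.max(np.abs(freqs - 0.25)) < 0.01

    def test_deterministic_given_seed(self, small_vae):
        a = small_vae.sample(100, seed=3)
        b = small_vae.sample(100, seed=3)
        assert np.array_equal(a.codes, b.codes)

    def test_z_independent_decoder_iid_from_bias(self, rng):
        m = zero_param_vae(N=3, q=3)
        m.params_["b_s"] = np.tile(np.log([0.6, 0.3, 0.1]), 3)
        s = m.sample(50_000, seed=4)
        for i in range(3):
            emp = np.bincount(s.codes[:, i], minlength=3) / 50_000
            assert np.max(np.abs(emp - [0.6, 0.3, 0.1])) < 0.01


class TestImportanceSampling:
    def test_z_independent_decoder_exact_for_any_k(self, rng):
        m = zero_param_vae(N=4, q=3)
        m.params_["b_s"] = rng.normal(size=12)
        codes = rng.integers(0, 3, size=(5, 4))
        logits = m.params_["b_s"].reshape(4, 3)
        lp = logits - logsumexp(logits, axis=1, keepdims=True)
        exact = -lp[np.arange(4)[None, :], codes].sum(axis=1)
        for K in (1, 10, 500):
            assert np.allclose(m.energy_importance(codes, K=K, seed=0), exact, atol=1e-9)

    def test_latent_one_matches_gauss_hermite_quadrature(self, small_vae):
        p = {k: v.copy() for k, v in small_vae.params_.items()}
        p["W_mu"], p["b_mu"] = p["W_mu"][:1], p["b_mu"][:1]
        p["W_sigma"], p["b_sigma"] = p["W_sigma"][:1], p["b_sigma"][:1]
        p["W_dec"] = p["W_dec"][:, :1]
        m = SequenceVAE.from_parameters(p, N=5, q=3)
        codes = np.array([[0, 1, 2, 1, 0]])
        x, w = hermegauss(100)
        lpz = m._decoder_logprob(x[:, None], np.repeat(codes, 100, axis=0))
        truth = -np.log(np.sum(w * np.exp(lpz)) / np.sqrt(2 * np.pi))
        reps = np.array([m.energy_importance(codes, K=5000, seed=s)[0] for s in range(10)])
        se = reps.std(ddof=1) / np.sqrt(len(reps))
        assert abs(reps.mean() - truth) < 3 * max(se, 1e-4)

    def test_estimates_converge_with_k(self, small_vae, rng):
        # a mild model (posterior close to the proposal) keeps the importance
        # weights well behaved, as for a trained VAE
        mild = SequenceVAE.from_parameters(
            {k: 0.4 * v for k, v in small_vae.params_.items()}, N=5, q=3
        )
        codes = rng.integers(0, 3, size=(20, 5))
        e1 = mild.energy_importance(codes, K=5000, seed=1)
        e2 = mild.energy_importance(codes, K=50_000, seed=2)
        assert np.max(np.abs(e1 - e2)) < 0.05

    def test_variance_decreases_with_k(self, small_vae):
        codes = np.array([[0, 1, 2, 1, 0]])
        small_k = [small_vae.energy_importance(codes, K=20, seed=s)[0] for s in range(30)]
        big_k = [small_vae.energy_importance(codes, K=2000, seed=s)[0] for s in range(30)]
        assert np.var(big_k) < np.var(small_k)

    def test_energy_flagged_as_estimate(self, small_vae):
        assert small_vae.energy_is_estimate is True
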