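"""VAE posterior, reparameterization, KL divergence and loss identities."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from aemol._autodiff import Tensor
from aemol.vae import (
    DecoderNet,
    GaussianPosterior,
    PriorSpec,
    SmilesVAE,
    kl_term,
    kl_to_standard_normal,
    reconstruction_nll,
    reparameterized_sample,
    vae_loss,
)


def kl_quadrature(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Per-coordinate numerical integration of the KL integrand (oracle)."""
    total = 0.0
    for m, lv in zip(mu.ravel(), logvar.ravel()):
        s = np.exp(0.5 * lv)
        f = lambda x: norm.pdf(x, m, s) * (
            norm.logpdf(x, m, s) - norm.logpdf(x, 0.0, 1.0)
        )
        lo, hi = m - 12 * s - 12, m + 12 * s + 12
        total += quad(f, lo, hi, limit=200)[0]
    return total


class TestKL:
    def test_standard_posterior_has_zero_kl(self):
        q = GaussianPosterior(mean=np.zeros(8), log_variance=np.zeros(8))
        assert kl_to_standard_normal(q) == pytest.approx(0.0, abs=1e-12)

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(100):
            mu = rng.normal(0, 2, size=4)
            logvar = rng.normal(0, 1, size=4)
            q = GaussianPosterior(mean=mu, log_variance=logvar)
            worst = max(worst, abs(kl_to_standard_normal(q) - kl_quadrature(mu, logvar)))
        assert worst <= 1e-6

    def test_nonnegative_on_random_posteriors(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            q = GaussianPosterior(
                mean=rng.normal(0, 3, 6), log_variance=rng.normal(0, 2, 6)
            )
            assert kl_to_standard_normal(q) >= 0.0

    def test_infinite_log_variance_rejected(self):
        with pytest.raises(ValueError):
            GaussianPosterior(mean=np.zeros(2), log_variance=np.array([0.0, np.inf]))


class TestReparameterization:
    def test_degenerate_variance_returns_mean(self):
        q = GaussianPosterior(mean=np.arange(4.0), log_variance=np.full(4, -80.0))
        z = reparameterized_sample(q, np.random.default_rng(0))
        np.testing.assert_allclose(z.ravel(), np.arange(4.0), atol=1e-12)

    def test_sample_mean_approaches_mu(self):
        mu = np.array([1.5, -2.0, 0.3])
        q = GaussianPosterior(mean=np.tile(mu, (100_000, 1)),
                              log_variance=np.zeros((100_000, 3)))
        z = reparameterized_sample(q, np.random.default_rng(5))
        bound = 4.0 / np.sqrt(100_000)
        assert np.all(np.abs(z.mean(axis=0) - mu) < bound)

    def test_fixed_seed_reproducible(self):
        q = GaussianPosterior(mean=np.zeros(6), log_variance=np.zeros(6))
        z1 = reparameterized_sample(q, np.random.default_rng(9))
        z2 = reparameterized_sample(q, np.random.default_rng(9))
        np.testing.assert_array_equal(z1, z2)


class TestVaeLoss:
    def test_perfect_prediction_and_standard_posterior_give_zero(self):
        B, L, V = 2, 5, 4
        target = np.zeros((B, L), dtype=int)
        logp = np.full((B, L, V), -1e9)
        logp[:, :, 0] = 0.0  # probability 1 on the target token
        loss = vae_loss(logp, target, np.zeros((B, 3)), np.zeros((B, 3)))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_closed_form(self):
        B, L, V = 3, 7, 5
        target = np.ones((B, L), dtype=int)
        logp = np.full((B, L, V), -np.log(V))
        loss = vae_loss(logp, target, np.zeros((B, 2)), np.zeros((B, 2)),
                        kl_weight=0.0)
        assert loss == pytest.approx(L * np.log(V), rel=1e-12)

    def test_zero_kl_weight_is_pure_reconstruction(self):
        rng = np.random.default_rng(1)
        B, L, V = 2, 4, 6
        raw = rng.standard_normal((B, L, V))
        logp = raw - np.log(np.exp(raw).sum(-1, keepdims=True))
        target = rng.integers(0, V, (B, L))
        mu = rng.standard_normal((B, 3))
        logvar = rng.standard_normal((B, 3))
        assert vae_loss(logp, target, mu, logvar, kl_weight=0.0) == pytest.approx(
            reconstruction_nll(logp, target), rel=1e-12
        )

    def test_matches_independent_reevaluation(self):
        """Loss formula vs a from-scratch float64 re-implementation."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            B, L, V, d = 3, 6, 5, 4
            raw = rng.standard_normal((B, L, V))
            logp = raw - np.log(np.exp(raw).sum(-1, keepdims=True))
            target = rng.integers(0, V, (B, L))
            mu = rng.standard_normal((B, d))
            logvar = rng.standard_normal((B, d))
            w = rng.random()
            # independent evaluation with explicit loops
            recon = 0.0
            for b in range(B):
                for t in range(L):
                    recon -= logp[b, t, target[b, t]]
            recon /= B
            kl = 0.0
            for b in range(B):
                for j in range(d):
                    kl -= 0.5 * (1 + logvar[b, j] - mu[b, j] ** 2
                                 - np.exp(logvar[b, j]))
            kl /= B
            expected = recon + w * kl
            assert vae_loss(logp, target, mu, logvar, w) == pytest.approx(
                expected, rel=1e-12
            )

    def test_tensor_and_numpy_paths_agree(self):
        rng = np.random.default_rng(2)
        B, L, V = 2, 3, 4
        raw = rng.standard_normal((B, L, V)).astype(np.float32)
        logp = raw - np.log(np.exp(raw).sum(-1, keepdims=True))
        target = rng.integers(0, V, (B, L))
        t_val = reconstruction_nll(Tensor(logp), target)
        np_val = reconstruction_nll(logp.astype(np.float64), target)
        assert float(t_val.data) == pytest.approx(np_val, rel=1e-5)


class TestPriorSpec:
    def test_gaussian_moments(self):
        p = PriorSpec(family="standard_gaussian")
        assert p.mean == 0.0 and p.variance == 1.0

    def test_uniform_bounds_validated(self):
        with pytest.raises(ValueError):
            PriorSpec(family="uniform", low=1.0, high=-1.0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(family="laplace")


class TestTeacherForcingContract:
    @staticmethod
    def _decoder(teacher_forcing):
        return DecoderNet(latent_dim=3, n_tokens=5, max_length=6, gru_dim=8,
                          teacher_forcing=teacher_forcing,
                          rng=np.random.default_rng(0))

    def test_without_forcing_output_ignores_target(self):
        dec = self._decoder(False)
        z = Tensor(np.random.default_rng(1).standard_normal((2, 3)).astype(np.float32))
        t1 = np.random.default_rng(2).integers(0, 5, (2, 6))
        t2 = np.random.default_rng(3).integers(0, 5, (2, 6))
        lp1 = dec.forward_train(z, t1).data
        lp2 = dec.forward_train(z, t2).data
        np.testing.assert_array_equal(lp1, lp2)

    def test_with_forcing_reads_only_past_positions(self):
        dec = self._decoder(True)
        z = Tensor(np.random.default_rng(1).standard_normal((1, 3)).astype(np.float32))
        base = np.array([[1, 2, 3, 4, 1, 2]])
        perturbed = base.copy()
        k = 3
        perturbed[0, k] = 0  # change target at position k
        lp1 = dec.forward_train(z, base).data
        lp2 = dec.forward_train(z, perturbed).data
        # predictions at positions <= k are conditioned on targets < k only
        np.testing.assert_array_equal(lp1[:, : k + 1], lp2[:, : k + 1])
        assert not np.array_equal(lp1[:, k + 1 :], lp2[:, k + 1 :])

    def test_rows_are_normalized_distributions(self):
        dec = self._decoder(True)
        z = Tensor(np.random.default_rng(4).standard_normal((2, 3)).astype(np.float32))
        lp = dec.forward_train(z, np.zeros((2, 6), dtype=int)).data
        np.testing.assert_allclose(np.exp(lp).sum(axis=-1), 1.0, atol=1e-5)


class TestPosterior:
    def test_encode_posterior_deterministic(self, teacher_vae, fixture_corpus):
        q1 = teacher_vae.encode_posterior(fixture_corpus[:3])
        q2 = teacher_vae.encode_posterior(fixture_corpus[:3])
        np.testing.assert_array_equal(q1.mean, q2.mean)
        np.testing.assert_array_equal(q1.log_variance, q2.log_variance)
        assert np.all(np.isfinite(q1.mean))

    def test_distinct_molecules_map_to_distinct_means(self, teacher_vae,
                                                      fixture_corpus):
        mu = teacher_vae.transform(fixture_corpus[:2])
        assert np.linalg.norm(mu[0] - mu[1]) > 1e-3

    def test_latent_dimension(self, teacher_vae, fixture_corpus):
        assert teacher_vae.transform(fixture_corpus[:1]).shape[1] == \
            teacher_vae.latent_dim

    def test_production_scale_default_latent_dim(self):
        assert SmilesVAE().latent_dim == 56
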