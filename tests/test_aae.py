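"""Adversarial losses, prior sampling and the three-step training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aemol.aae import (
    Discriminator,
    SmilesAAE,
    aae_training_step,
    discriminator_loss,
    generator_loss,
    sample_prior,
)
from aemol.nn import Adam
from aemol.vae import DecoderNet, EncoderNet, PriorSpec


class TestDiscriminatorLoss:
    def test_perfect_discriminator_limit(self):
        assert discriminator_loss(1.0, 0.0) == pytest.approx(0.0, abs=1e-5)

    def test_coin_flip_closed_form(self):
        assert discriminator_loss(0.5, 0.5) == pytest.approx(2 * np.log(2), rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        d_real = rng.uniform(1e-6, 1 - 1e-6, size=8)
        d_fake = rng.uniform(1e-6, 1 - 1e-6, size=8)
        expected = -(np.log(d_real).mean() + np.log(1 - d_fake).mean())
        assert discriminator_loss(d_real, d_fake) == pytest.approx(expected, rel=1e-12)


class TestGeneratorLoss:
    def test_fooled_discriminator_gives_zero(self):
        assert generator_loss(1.0) == pytest.approx(0.0, abs=1e-6)

    def test_exp_minus_one_closed_form(self):
        assert generator_loss(np.exp(-1.0)) == pytest.approx(1.0, rel=1e-12)

    def test_monotone_decreasing_in_d_fake(self):
        rng = np.random.default_rng(17)
        pairs = np.sort(rng.uniform(1e-6, 1 - 1e-6, size=(1000, 2)), axis=1)
        for d1, d2 in pairs:
            if d1 == d2:
                continue
            assert generator_loss(d1) > generator_loss(d2)


class TestSamplePrior:
    def test_gaussian_clt_bound(self):
        p = PriorSpec(family="standard_gaussian")
        z = sample_prior(p, 100_000, 3, np.random.default_rng(0))
        assert np.all(np.abs(z.mean(axis=0)) < 4 / np.sqrt(100_000))

    def test_uniform_support(self):
        p = PriorSpec(family="uniform", low=-1, high=1)
        z = sample_prior(p, 5000, 4, np.random.default_rng(1))
        assert z.min() >= -1 and z.max() <= 1

    def test_fixed_seed_identical(self):
        p = PriorSpec(family="uniform", low=-1, high=1)
        z1 = sample_prior(p, 10, 2, np.random.default_rng(3))
        z2 = sample_prior(p, 10, 2, np.random.default_rng(3))
        np.testing.assert_array_equal(z1, z2)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            sample_prior(PriorSpec(), 0, 2, np.random.default_rng(0))


def _tiny_models(V=6, L=5, d=3, seed=0):
    rng = np.random.default_rng(seed)
    enc = EncoderNet(V, L, (4, 4, 4), 2, 16, d, rng)
    dec = DecoderNet(d, V, L, 8, True, rng)
    disc = Discriminator(d, (8, 8), rng)
    return enc, dec, disc


class TestTrainingStep:
    def _run(self, adversarial):
        enc, dec, disc = _tiny_models()
        opts = (
            Adam(enc.parameters() + dec.parameters(), lr=1e-3),
            Adam(disc.parameters(), lr=1e-3),
            Adam(enc.parameters(), lr=1e-3),
        )
        batch = np.random.default_rng(2).integers(0, 6, (4, 5))
        snap = lambda m: [p.data.copy() for p in m.parameters()]
        before = (snap(enc), snap(dec), snap(disc))
        rep = aae_training_step(batch, enc, dec, disc, *opts,
                                prior=PriorSpec(), rng=np.random.default_rng(3),
                                adversarial=adversarial)
        after = (snap(enc), snap(dec), snap(disc))
        return rep, before, after

    def test_all_three_steps_update_their_networks(self):
        rep, before, after = self._run(adversarial=True)
        for b, a in zip(before, after):  # encoder, decoder, discriminator
            assert any(not np.array_equal(x, y) for x, y in zip(b, a))
        assert rep.discriminator_loss >= 0.0
        assert np.isfinite(rep.reconstruction_loss)

    def test_ablation_reduces_to_plain_autoencoder(self):
        rep, before, after = self._run(adversarial=False)
        assert rep.discriminator_loss == 0.0 and rep.generator_loss == 0.0
        # discriminator untouched
        assert all(np.array_equal(x, y) for x, y in zip(before[2], after[2]))
        # encoder/decoder updated by the reconstruction step
        assert any(not np.array_equal(x, y) for x, y in zip(before[0], after[0]))

    def test_step_ordering_observable(self):
        """Parameter snapshots differ after each of the three sub-steps."""
        enc, dec, disc = _tiny_models(seed=5)
        opt1 = Adam(enc.parameters() + dec.parameters(), lr=1e-3)
        opt2 = Adam(disc.parameters(), lr=1e-3)
        opt3 = Adam(enc.parameters(), lr=1e-3)
        batch = np.random.default_rng(0).integers(0, 6, (3, 5))
        enc_before_all = [p.data.copy() for p in enc.parameters()]
        # after step 1 only (ablated run): encoder changed once
        aae_training_step(batch, enc, dec, disc, opt1, opt2, opt3,
                          prior=PriorSpec(), rng=np.random.default_rng(1),
                          adversarial=False)
        enc_after_recon = [p.data.copy() for p in enc.parameters()]
        disc_after_recon = [p.data.copy() for p in disc.parameters()]
        # full loop: discriminator changes in step 2, encoder changes again in step 3
        aae_training_step(batch, enc, dec, disc, opt1, opt2, opt3,
                          prior=PriorSpec(), rng=np.random.default_rng(2),
                          adversarial=True)
        disc_after_full = [p.data.copy() for p in disc.parameters()]
        assert any(not np.array_equal(a, b)
                   for a, b in zip(enc_before_all, enc_after_recon))
        assert any(not np.array_equal(a, b)
                   for a, b in zip(disc_after_recon, disc_after_full))


class TestConfigValidation:
    def test_teacher_forcing_cannot_be_disabled(self):
        model = SmilesAAE(teacher_forcing=False, latent_dim=4, max_length=20,
                          n_epochs=1)
        with pytest.raises(ValueError, match="teacher forcing"):
            model.fit(["CCCCCCCCCC", "CCCCCCCCCO"])

    def test_unknown_prior_rejected(self):
        with pytest.raises(ValueError):
            SmilesAAE(prior="cauchy").prior_spec()

    def test_uniform_prior_spec_uses_bounds(self):
        spec = SmilesAAE(prior="uniform", uniform_bounds=(-2, 2)).prior_spec()
        assert spec.low == -2 and spec.high == 2 and spec.variance == pytest.approx(4 / 3)
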