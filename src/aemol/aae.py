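"""Adversarial autoencoder: deterministic encoder + discriminator-shaped prior.

Instead of a KL penalty, a discriminator network D is trained to tell encoder
outputs z from draws z' of a target prior (standard Gaussian or per-coordinate
uniform), and the encoder is trained to fool it.  Each mini-batch runs three
sequential updates:

1. encoder + decoder minimize the reconstruction loss,
2. the discriminator minimizes  -(log D(z') + log(1 - D(z))),
3. the encoder minimizes        -log D(z).

The encoder here maps a molecule directly to a latent point (no sampling);
the decoder always uses teacher forcing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import codec
from ._autodiff import Tensor, no_grad
from .nn import Adam, Dense, Module
from .vae import (
    DecoderNet,
    EncoderNet,
    PriorSpec,
    SmilesVAE,
    reconstruction_nll,
)

PROB_EPS = 1e-7  # clamp before logs so a saturated discriminator stays finite


@dataclass
class AdversarialBatchReport:
    reconstruction_loss: float
    discriminator_loss: float
    generator_loss: float

    def __post_init__(self):
        for v in (self.reconstruction_loss, self.discriminator_loss,
                  self.generator_loss):
            if not np.isfinite(v):
                raise FloatingPointError("non-finite adversarial loss")


class Discriminator(Module):
    """Three dense layers: affine, affine+SELU, affine+sigmoid."""

    def __init__(self, latent_dim: int, hidden=(256, 256), rng=None):
        rng = rng or np.random.default_rng(0)
        self.fc1 = Dense(latent_dim, hidden[0], rng)
        self.fc2 = Dense(hidden[0], hidden[1], rng)
        self.fc3 = Dense(hidden[1], 1, rng)

    def __call__(self, z: Tensor) -> Tensor:
        return self.fc3(self.fc2(self.fc1(z)).selu()).sigmoid()


def _clamp(d: Tensor) -> Tensor:
    # straight-through clamp: gradients pass unchanged, values stay in (0,1)
    clipped = np.clip(d.data, PROB_EPS, 1.0 - PROB_EPS)
    return d + Tensor(clipped - d.data)


def discriminator_loss(d_real, d_fake):
    """-(log D(z') + log(1 - D(z))), averaged over the batch.

    Tensor inputs keep the graph (training path); plain arrays or floats are
    evaluated in float64.
    """
    if isinstance(d_real, Tensor) or isinstance(d_fake, Tensor):
        d_real = _clamp(d_real if isinstance(d_real, Tensor) else Tensor(d_real))
        d_fake = _clamp(d_fake if isinstance(d_fake, Tensor) else Tensor(d_fake))
        return -(d_real.log().mean() + (1.0 - d_fake).log().mean())
    d_real = np.clip(np.asarray(d_real, dtype=np.float64), PROB_EPS, 1 - PROB_EPS)
    d_fake = np.clip(np.asarray(d_fake, dtype=np.float64), PROB_EPS, 1 - PROB_EPS)
    return float(-(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake))))


def generator_loss(d_fake):
    """-log D(z), averaged over the batch; the encoder's fooling objective."""
    if isinstance(d_fake, Tensor):
        return -_clamp(d_fake).log().mean()
    d_fake = np.clip(np.asarray(d_fake, dtype=np.float64), PROB_EPS, 1 - PROB_EPS)
    return float(-np.mean(np.log(d_fake)))


def sample_prior(prior: PriorSpec, n: int, latent_dim: int,
                 rng: np.random.Generator) -> np.ndarray:
    """i.i.d. draws z' from the target prior, shape (n, latent_dim)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if prior.family == "standard_gaussian":
        return rng.standard_normal((n, latent_dim))
    return rng.uniform(prior.low, prior.high, size=(n, latent_dim))


def aae_training_step(batch_idx: np.ndarray, encoder: EncoderNet,
                      decoder: DecoderNet, discriminator: Discriminator,
                      opt_recon: Adam, opt_disc: Adam, opt_gen: Adam,
                      prior: PriorSpec, rng: np.random.Generator,
                      adversarial: bool = True) -> AdversarialBatchReport:
    """One three-step adversarial update on a mini-batch of index sequences.

    With ``adversarial=False`` steps 2-3 are skipped and the loop reduces to
    a plain deterministic autoencoder update.
    """
    V = decoder.n_tokens
    eye = np.eye(V, dtype=np.float32)
    x = eye[batch_idx]

    # step 1: reconstruction
    z = encoder(Tensor(x))
    logp = decoder.forward_train(z, batch_idx)
    recon = reconstruction_nll(logp, batch_idx)
    opt_recon.zero_grad()
    recon.backward()
    opt_recon.step()

    if not adversarial:
        return AdversarialBatchReport(float(recon.data), 0.0, 0.0)

    # step 2: discriminator on fresh prior draws vs detached encoder output
    with no_grad():
        z_fake = encoder(Tensor(x)).data
    z_real = sample_prior(prior, batch_idx.shape[0], z_fake.shape[1], rng)
    d_loss = discriminator_loss(
        discriminator(Tensor(z_real.astype(np.float32))),
        discriminator(Tensor(z_fake)),
    )
    opt_disc.zero_grad()
    d_loss.backward()
    opt_disc.step()

    # step 3: encoder fools the (frozen) discriminator
    z = encoder(Tensor(x))
    disc_params = discriminator.parameters()
    for p in disc_params:
        p.requires_grad = False
    try:
        g_loss = generator_loss(discriminator(z))
        opt_gen.zero_grad()
        g_loss.backward()
        opt_gen.step()
    finally:
        for p in disc_params:
            p.requires_grad = True

    return AdversarialBatchReport(
        float(recon.data), float(d_loss.data), float(g_loss.data)
    )


class SmilesAAE(SmilesVAE):
    """Adversarial autoencoder over SMILES.

    Shares the encoder/decoder architecture with :class:`SmilesVAE` but the
    encoder output is the latent point itself and the prior is imposed
    adversarially.  ``prior`` selects the target distribution:
    ``"gaussian"`` (N(0, I)) or ``"uniform"`` (per-coordinate on
    ``uniform_bounds``).  Teacher forcing is mandatory.
    """

    def __init__(self, latent_dim=56, max_length=120, prior="gaussian",
                 uniform_bounds=(-1.0, 1.0), conv_channels=(8, 8, 8),
                 kernel_size=5, dense_dim=128, gru_dim=64,
                 disc_hidden=(256, 256), batch_size=500,
                 learning_rate=3.1e-4, adv_learning_rate=None,
                 n_epochs=200, stop_accuracy=None,
                 eval_every=10, teacher_forcing=True, vocab=None,
                 random_state=0):
        self.latent_dim = latent_dim
        self.max_length = max_length
        self.prior = prior
        self.uniform_bounds = uniform_bounds
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.dense_dim = dense_dim
        self.gru_dim = gru_dim
        self.disc_hidden = disc_hidden
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.adv_learning_rate = adv_learning_rate
        self.n_epochs = n_epochs
        self.stop_accuracy = stop_accuracy
        self.eval_every = eval_every
        self.teacher_forcing = teacher_forcing
        self.vocab = vocab
        self.random_state = random_state

    def prior_spec(self) -> PriorSpec:
        if self.prior == "gaussian":
            return PriorSpec(family="standard_gaussian")
        if self.prior == "uniform":
            low, high = self.uniform_bounds
            return PriorSpec(family="uniform", low=low, high=high)
        raise ValueError(f"unknown prior {self.prior!r}")

    def _build(self, rng: np.random.Generator) -> None:
        if not self.teacher_forcing:
            raise ValueError("the adversarial decoder always uses teacher forcing")
        V = len(self.vocab_)
        self.encoder_ = EncoderNet(
            V, self.max_length, tuple(self.conv_channels), self.kernel_size,
            self.dense_dim, self.latent_dim, rng,
        )
        self.decoder_ = DecoderNet(
            self.latent_dim, V, self.max_length, self.gru_dim, True, rng,
        )
        self.discriminator_ = Discriminator(
            self.latent_dim, tuple(self.disc_hidden), rng
        )

    def fit(self, X, y=None):
        X = list(X)
        if not X:
            raise ValueError("empty training corpus")
        prior = self.prior_spec()
        rng = np.random.default_rng(self.random_state)
        self.vocab_ = self.vocab or codec.build_vocabulary(X, self.max_length)
        if self.vocab_.max_length != self.max_length:
            raise ValueError("vocabulary max_length disagrees with model")
        self._build(rng)
        idx_all = codec.encode_corpus(X, self.vocab_)
        eye = np.eye(len(self.vocab_), dtype=np.float32)
        opt_recon = Adam(
            self.encoder_.parameters() + self.decoder_.parameters(),
            lr=self.learning_rate,
        )
        adv_lr = self.adv_learning_rate or self.learning_rate
        opt_disc = Adam(self.discriminator_.parameters(), lr=adv_lr)
        opt_gen = Adam(self.encoder_.parameters(), lr=adv_lr)
        n = len(X)
        self.history_ = []
        self.n_iter_ = 0
        for epoch in range(self.n_epochs):
            order = rng.permutation(n)
            sums = np.zeros(3)
            for start in range(0, n, self.batch_size):
                batch = idx_all[order[start : start + self.batch_size]]
                rep = aae_training_step(
                    batch, self.encoder_, self.decoder_, self.discriminator_,
                    opt_recon, opt_disc, opt_gen, prior, rng,
                )
                sums += (rep.reconstruction_loss, rep.discriminator_loss,
                         rep.generator_loss)
                self.n_iter_ += 1
            n_batches = int(np.ceil(n / self.batch_size))
            record = {
                "epoch": epoch,
                "reconstruction_loss": sums[0] / n_batches,
                "discriminator_loss": sums[1] / n_batches,
                "generator_loss": sums[2] / n_batches,
            }
            if self.stop_accuracy is not None and (epoch + 1) % self.eval_every == 0:
                acc = self._training_accuracy(idx_all, eye)
                record["train_char_accuracy"] = acc
                self.history_.append(record)
                if acc >= self.stop_accuracy:
                    break
            else:
                self.history_.append(record)
        return self

    # the AAE encoder is deterministic: its output is the latent point
    def _latent_tensor(self, x_onehot: np.ndarray) -> Tensor:
        return self.encoder_(Tensor(x_onehot))

    def _training_accuracy(self, idx_all, eye):
        with no_grad():
            z = self._latent_tensor(eye[idx_all])
            logp = self.decoder_.forward_train(z, idx_all)
        pred = np.argmax(logp.data, axis=-1)
        return float(np.mean(pred == idx_all))

    def transform(self, X) -> np.ndarray:
        self._check_fitted()
        idx = codec.encode_corpus(list(X), self.vocab_)
        eye = np.eye(len(self.vocab_), dtype=np.float32)
        with no_grad():
            z = self._latent_tensor(eye[idx])
        return np.asarray(z.data, dtype=np.float64)

    def encode_posterior(self, X):
        raise NotImplementedError(
            "the adversarial encoder is deterministic; use transform()"
        )

    def predict_train_tokens(self, X) -> np.ndarray:
        self._check_fitted()
        idx = codec.encode_corpus(list(X), self.vocab_)
        eye = np.eye(len(self.vocab_), dtype=np.float32)
        with no_grad():
            z = self._latent_tensor(eye[idx])
            logp = self.decoder_.forward_train(z, idx)
        return np.argmax(logp.data, axis=-1)

    def discriminator_accuracy(self, X, n_prior: int | None = None,
                               random_state: int = 0) -> float:
        """Held-out real/fake accuracy: fresh prior draws vs encoder outputs."""
        self._check_fitted()
        rng = np.random.default_rng(random_state)
        z_fake = self.transform(X).astype(np.float32)
        n_prior = n_prior or len(z_fake)
        z_real = sample_prior(self.prior_spec(), n_prior, self.latent_dim, rng)
        with no_grad():
            d_fake = self.discriminator_(Tensor(z_fake)).data.ravel()
            d_real = self.discriminator_(Tensor(z_real.astype(np.float32))).data.ravel()
        correct = np.sum(d_real > 0.5) + np.sum(d_fake <= 0.5)
        return float(correct / (len(d_real) + len(d_fake)))

    def save(self, path) -> None:
        import json as _json

        self._check_fitted()
        arrays = {f"enc_{i}": a for i, a in enumerate(self.encoder_.state_arrays())}
        arrays.update(
            {f"dec_{i}": a for i, a in enumerate(self.decoder_.state_arrays())}
        )
        arrays.update(
            {f"disc_{i}": a
             for i, a in enumerate(self.discriminator_.state_arrays())}
        )
        meta = {
            "class": type(self).__name__,
            "config": self._config_dict(),
            "vocab": {"tokens": list(self.vocab_.tokens),
                      "max_length": self.vocab_.max_length},
        }
        np.savez(path, __meta__=np.frombuffer(
            _json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "SmilesAAE":
        import json as _json

        with np.load(path) as data:
            meta = _json.loads(bytes(data["__meta__"]).decode())
            model = cls(**meta["config"])
            model.vocab_ = codec.TokenVocabulary(
                tokens=tuple(meta["vocab"]["tokens"]),
                max_length=meta["vocab"]["max_length"],
            )
            model._build(np.random.default_rng(model.random_state))
            model.encoder_.load_arrays(
                [data[f"enc_{i}"] for i in range(len(model.encoder_.parameters()))]
            )
            model.decoder_.load_arrays(
                [data[f"dec_{i}"] for i in range(len(model.decoder_.parameters()))]
            )
            model.discriminator_.load_arrays(
                [data[f"disc_{i}"]
                 for i in range(len(model.discriminator_.parameters()))]
            )
        model.history_ = []
        return model
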