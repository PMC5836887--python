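"""Variational autoencoder over SMILES sequences.

The encoder is a stack of three 1-d convolutions followed by two fully
connected layers whose output parameterizes a diagonal Gaussian posterior
q(z|X) over a continuous latent space (56-dimensional by default).  The
decoder maps a latent point through a fully connected layer into a stack of
three GRU layers that emit a token distribution at every position of the
fixed-length output sequence.

Two decoding regimes are supported.  With *teacher forcing* the last GRU
layer's input at step t is the concatenation of the previous layer's output
and the token at t-1 — the target token during training, the sampled token
during generation.  Without teacher forcing the last layer sees only the
previous layer's output, in both modes, so the output distribution depends on
the latent point alone.

Training minimizes the negative evidence lower bound: reconstruction negative
log-likelihood summed over all sequence positions (padding included) plus a
KL divergence term pulling q(z|X) toward the standard normal prior.  The KL
weight is annealed linearly from 0 to its final value; a constant weight of 1
recovers the plain ELBO.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import codec
from ._autodiff import Tensor, concat, gather_last, log_softmax, no_grad
from .nn import Adam, Conv1d, Dense, GRUCell, Module


@dataclass
class GaussianPosterior:
    """Diagonal Gaussian q(z|X): per-coordinate mean and log-variance."""

    mean: np.ndarray
    log_variance: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=np.float64))
        self.log_variance = np.atleast_2d(
            np.asarray(self.log_variance, dtype=np.float64)
        )
        if self.mean.shape != self.log_variance.shape:
            raise ValueError("mean and log_variance shapes differ")
        if not np.all(np.isfinite(self.log_variance)):
            raise ValueError("log_variance must be finite")


@dataclass(frozen=True)
class PriorSpec:
    """Latent prior p(z): standard Gaussian or per-coordinate uniform."""

    family: str = "standard_gaussian"
    low: float = -1.0
    high: float = 1.0

    def __post_init__(self):
        if self.family not in ("standard_gaussian", "uniform"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "uniform" and not (
            np.isfinite(self.low) and np.isfinite(self.high) and self.low < self.high
        ):
            raise ValueError("uniform prior needs finite low < high")

    @property
    def mean(self) -> float:
        return 0.0 if self.family == "standard_gaussian" else (self.low + self.high) / 2

    @property
    def variance(self) -> float:
        if self.family == "standard_gaussian":
            return 1.0
        return (self.high - self.low) ** 2 / 12.0


def kl_to_standard_normal(q: GaussianPosterior) -> float:
    """D_KL(q || N(0, I)) = -1/2 sum(1 + log s^2 - mu^2 - s^2), batch-averaged."""
    var = np.exp(q.log_variance)
    per = -0.5 * np.sum(1.0 + q.log_variance - q.mean**2 - var, axis=1)
    return float(np.mean(per))


def reparameterized_sample(q: GaussianPosterior, rng: np.random.Generator) -> np.ndarray:
    """z = mu + sigma * eps with eps ~ N(0, I)."""
    eps = rng.standard_normal(q.mean.shape)
    return q.mean + np.exp(0.5 * q.log_variance) * eps


class EncoderNet(Module):
    """Three 1-d convolutions + two dense layers, SELU activations."""

    def __init__(self, n_tokens, max_length, conv_channels, kernel_size,
                 dense_dim, out_dim, rng):
        chans = [n_tokens, *conv_channels]
        self.convs = [
            Conv1d(chans[i], chans[i + 1], kernel_size, rng) for i in range(3)
        ]
        flat = (max_length - 3 * (kernel_size - 1)) * conv_channels[-1]
        if flat <= 0:
            raise ValueError("kernel too large for max_length")
        self.fc1 = Dense(flat, dense_dim, rng)
        self.fc2 = Dense(dense_dim, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).selu()
        B = h.shape[0]
        h = h.reshape(B, -1)
        return self.fc2(self.fc1(h).selu())


class DecoderNet(Module):
    """Dense latent projection + three GRU layers + output token head.

    The projected latent initializes every GRU state and is re-fed as the
    first layer's input at each step; with teacher forcing the last layer
    additionally receives the previous token as a one-hot vector.
    """

    def __init__(self, latent_dim, n_tokens, max_length, gru_dim,
                 teacher_forcing, rng):
        self.n_tokens = n_tokens
        self.max_length = max_length
        self.gru_dim = gru_dim
        self.teacher_forcing = teacher_forcing
        self.fc_z = Dense(latent_dim, gru_dim, rng)
        self.gru1 = GRUCell(gru_dim, gru_dim, rng)
        self.gru2 = GRUCell(gru_dim, gru_dim, rng)
        last_in = gru_dim + (n_tokens if teacher_forcing else 0)
        self.gru3 = GRUCell(last_in, gru_dim, rng)
        self.out = Dense(gru_dim, n_tokens, rng)

    def _init_state(self, z: Tensor):
        c = self.fc_z(z).selu()
        return c, c, c, c  # input context + three layer states

    def forward_train(self, z: Tensor, target_idx: np.ndarray) -> Tensor:
        """Log-probabilities (B, L, V) with the training-time input regime."""
        B = z.shape[0]
        V = self.n_tokens
        c, h1, h2, h3 = self._init_state(z)
        eye = np.eye(V, dtype=np.float32)
        outs = []
        for t in range(self.max_length):
            h1 = self.gru1(c, h1)
            h2 = self.gru2(h1, h2)
            if self.teacher_forcing:
                if t == 0:
                    prev = np.zeros((B, V), dtype=np.float32)
                    prev[:, 0] = 1.0  # pad plays the start symbol
                else:
                    prev = eye[target_idx[:, t - 1]]
                x3 = concat([h2, Tensor(prev)], axis=1)
            else:
                x3 = h2
            h3 = self.gru3(x3, h3)
            outs.append(h3.reshape(B, 1, self.gru_dim))
        seq = concat(outs, axis=1).reshape(B * self.max_length, self.gru_dim)
        logits = self.out(seq)
        return log_softmax(logits, axis=-1).reshape(B, self.max_length, V)

    def sample(self, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Generation mode: sample token sequences, feeding back samples.

        Returns an int index matrix (B, max_length).  Tokens are drawn from
        the raw output distribution (temperature 1) via the Gumbel-argmax
        identity; with teacher forcing the sampled token is the next step's
        feedback, otherwise the chain is token-independent.
        """
        B = z.shape[0]
        V = self.n_tokens
        eye = np.eye(V, dtype=np.float32)
        with no_grad():
            c, h1, h2, h3 = self._init_state(Tensor(z))
            prev = np.zeros((B, V), dtype=np.float32)
            prev[:, 0] = 1.0
            samples = np.empty((B, self.max_length), dtype=np.int64)
            for t in range(self.max_length):
                h1 = self.gru1(c, h1)
                h2 = self.gru2(h1, h2)
                x3 = concat([h2, Tensor(prev)], axis=1) if self.teacher_forcing else h2
                h3 = self.gru3(x3, h3)
                logp = log_softmax(self.out(h3), axis=-1).data
                gumbel = -np.log(-np.log(rng.random((B, V)) + 1e-12) + 1e-12)
                tok = np.argmax(logp + gumbel, axis=1)
                samples[:, t] = tok
                if self.teacher_forcing:
                    prev = eye[tok]
        return samples


def reconstruction_nll(logp, target_idx: np.ndarray):
    """Negative log-likelihood summed over every position, batch-averaged.

    Accepts the decoder's (B, L, V) log-probabilities either as a graph
    :class:`Tensor` (training path) or a plain numpy array (evaluation path,
    computed in the array's own dtype).
    """
    target_idx = np.asarray(target_idx)
    if isinstance(logp, Tensor):
        picked = gather_last(logp, target_idx)  # (B, L)
        return -picked.sum() / float(target_idx.shape[0])
    B, L = target_idx.shape
    picked = logp[np.arange(B)[:, None], np.arange(L)[None, :], target_idx]
    return -picked.sum() / B


def kl_term(mu, logvar):
    """Batch-averaged D_KL(q || N(0, I)) from mean / log-variance arrays."""
    if isinstance(mu, Tensor):
        per = (logvar.exp() + mu * mu - logvar - 1.0).sum() * 0.5
        return per / float(mu.shape[0])
    return 0.5 * np.sum(np.exp(logvar) + mu * mu - logvar - 1.0) / mu.shape[0]


def vae_loss(logp, target_idx: np.ndarray, mu, logvar, kl_weight: float = 1.0):
    """Negative ELBO: reconstruction NLL + kl_weight * D_KL(q || N(0,I))."""
    loss = reconstruction_nll(logp, target_idx)
    if kl_weight != 0.0:
        loss = loss + kl_weight * kl_term(mu, logvar)
    return loss


class SmilesVAE(BaseEstimator, TransformerMixin):
    """Variational autoencoder mapping SMILES to a continuous latent space.

    Parameters
    ----------
    latent_dim : dimensionality of the latent space (production-scale default 56).
    max_length : tokens per padded sequence.
    teacher_forcing : feed the previous token into the last decoder layer.
    conv_channels, kernel_size, dense_dim, gru_dim : network widths (defaults
        sized for desk-scale corpora; large-corpus work should widen them).
    kl_weight, kl_anneal_epochs : final KL weight and linear ramp length.
    batch_size, learning_rate, n_epochs : Adam training schedule.
    stop_accuracy : optional early stop once training-mode character accuracy
        (argmax predictions at the posterior mean) reaches this fraction.
    vocab : optional pre-built :class:`~aemol.codec.TokenVocabulary`; built
        from the training corpus when absent.
    random_state : seed for initialization, shuffling and latent sampling.
    """

    _estimator_type = "transformer"

    def __init__(self, latent_dim=56, max_length=120, teacher_forcing=True,
                 conv_channels=(8, 8, 8), kernel_size=5, dense_dim=128,
                 gru_dim=64, kl_weight=1.0, kl_anneal_epochs=50,
                 batch_size=500, learning_rate=3.1e-4, n_epochs=200,
                 stop_accuracy=None, eval_every=10, vocab=None,
                 random_state=0):
        self.latent_dim = latent_dim
        self.max_length = max_length
        self.teacher_forcing = teacher_forcing
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.dense_dim = dense_dim
        self.gru_dim = gru_dim
        self.kl_weight = kl_weight
        self.kl_anneal_epochs = kl_anneal_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.stop_accuracy = stop_accuracy
        self.eval_every = eval_every
        self.vocab = vocab
        self.random_state = random_state

    # -- construction helpers ------------------------------------------------
    def _build(self, rng: np.random.Generator) -> None:
        V = len(self.vocab_)
        self.encoder_ = EncoderNet(
            V, self.max_length, tuple(self.conv_channels), self.kernel_size,
            self.dense_dim, 2 * self.latent_dim, rng,
        )
        self.decoder_ = DecoderNet(
            self.latent_dim, V, self.max_length, self.gru_dim,
            self.teacher_forcing, rng,
        )

    def _posterior_tensors(self, x_onehot: np.ndarray):
        out = self.encoder_(Tensor(x_onehot))
        d = self.latent_dim
        return out[:, :d], out[:, d:]

    def _kl_schedule(self, epoch: int) -> float:
        if self.kl_anneal_epochs and self.kl_anneal_epochs > 0:
            ramp = min(1.0, (epoch + 1) / self.kl_anneal_epochs)
        else:
            ramp = 1.0
        return self.kl_weight * ramp

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y=None):
        """Train on a list of SMILES strings."""
        X = list(X)
        if not X:
            raise ValueError("empty training corpus")
        rng = np.random.default_rng(self.random_state)
        self.vocab_ = self.vocab or codec.build_vocabulary(X, self.max_length)
        if self.vocab_.max_length != self.max_length:
            raise ValueError("vocabulary max_length disagrees with model")
        self._build(rng)
        idx_all = codec.encode_corpus(X, self.vocab_)
        eye = np.eye(len(self.vocab_), dtype=np.float32)
        params = self.encoder_.parameters() + self.decoder_.parameters()
        opt = Adam(params, lr=self.learning_rate)
        n = len(X)
        self.history_ = []
        self.n_iter_ = 0
        for epoch in range(self.n_epochs):
            order = rng.permutation(n)
            klw = self._kl_schedule(epoch)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                batch = idx_all[order[start : start + self.batch_size]]
                x = eye[batch]
                mu, logvar = self._posterior_tensors(x)
                eps = rng.standard_normal(mu.shape).astype(np.float32)
                z = mu + (logvar * 0.5).exp() * Tensor(eps)
                logp = self.decoder_.forward_train(z, batch)
                loss = vae_loss(logp, batch, mu, logvar, kl_weight=klw)
                if not np.isfinite(loss.data):
                    raise FloatingPointError("training diverged (non-finite loss)")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * batch.shape[0]
                self.n_iter_ += 1
            record = {"epoch": epoch, "loss": epoch_loss / n, "kl_weight": klw}
            if self.stop_accuracy is not None and (epoch + 1) % self.eval_every == 0:
                acc = self._training_accuracy(idx_all, eye)
                record["train_char_accuracy"] = acc
                self.history_.append(record)
                if acc >= self.stop_accuracy:
                    break
            else:
                self.history_.append(record)
        return self

    def _training_accuracy(self, idx_all: np.ndarray, eye: np.ndarray) -> float:
        with no_grad():
            mu, _ = self._posterior_tensors(eye[idx_all])
            logp = self.decoder_.forward_train(mu, idx_all)
        pred = np.argmax(logp.data, axis=-1)
        return float(np.mean(pred == idx_all))

    def encode_posterior(self, X) -> GaussianPosterior:
        """Gaussian posterior q(z|X) for a list of SMILES."""
        self._check_fitted()
        idx = codec.encode_corpus(list(X), self.vocab_)
        eye = np.eye(len(self.vocab_), dtype=np.float32)
        with no_grad():
            mu, logvar = self._posterior_tensors(eye[idx])
        return GaussianPosterior(mean=mu.data, log_variance=logvar.data)

    def transform(self, X) -> np.ndarray:
        """Latent representation (posterior mean) of each SMILES."""
        return self.encode_posterior(X).mean

    def latent_of(self, X) -> np.ndarray:
        return self.transform(X)

    def sample_tokens(self, z: np.ndarray, n_samples: int,
                      rng: np.random.Generator) -> np.ndarray:
        """Sample ``n_samples`` token sequences from one latent point."""
        self._check_fitted()
        z = np.atleast_2d(np.asarray(z, dtype=np.float32))
        if z.shape != (1, self.latent_dim):
            raise ValueError(f"expected one latent point of dim {self.latent_dim}")
        tiled = np.repeat(z, n_samples, axis=0)
        return self.decoder_.sample(tiled, rng)

    def predict_train_tokens(self, X) -> np.ndarray:
        """Argmax token predictions in training mode at the posterior mean."""
        self._check_fitted()
        idx = codec.encode_corpus(list(X), self.vocab_)
        eye = np.eye(len(self.vocab_), dtype=np.float32)
        with no_grad():
            mu, _ = self._posterior_tensors(eye[idx])
            logp = self.decoder_.forward_train(mu, idx)
        return np.argmax(logp.data, axis=-1)

    def inverse_transform(self, Z, n_samples=500, random_state=0):
        """Consensus SMILES for each latent row (None when nothing decodes)."""
        from .generate import generate

        rng = np.random.default_rng(random_state)
        Z = np.atleast_2d(Z)
        return [
            generate(self, z, n_samples=n_samples, rng=rng).consensus_smiles
            for z in Z
        ]

    def _check_fitted(self):
        if not hasattr(self, "decoder_"):
            raise RuntimeError("model is not fitted")

    # -- persistence ---------------------------------------------------------
    def _config_dict(self) -> dict:
        cfg = self.get_params()
        cfg.pop("vocab")
        return cfg

    def save(self, path: str | Path) -> None:
        """Persist config, vocabulary and weights to one ``.npz`` checkpoint."""
        self._check_fitted()
        arrays = {
            f"enc_{i}": a for i, a in enumerate(self.encoder_.state_arrays())
        }
        arrays.update(
            {f"dec_{i}": a for i, a in enumerate(self.decoder_.state_arrays())}
        )
        meta = {
            "class": type(self).__name__,
            "config": self._config_dict(),
            "vocab": {"tokens": list(self.vocab_.tokens),
                      "max_length": self.vocab_.max_length},
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SmilesVAE":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
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
        model.history_ = []
        return model
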