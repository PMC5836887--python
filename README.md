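# aemol

Generative autoencoders over SMILES for de novo molecular design: encode
molecules into a continuous latent space, decode latent points back into
molecules, quantify how well the latent space preserves chemical
similarity, and search it with Bayesian optimization against a QSAR
activity model.

## Who this is for

Computational chemists and method developers who want a compact,
CPU-friendly, fully inspectable implementation of the
generative-autoencoder approach to inverse QSAR: instead of inverting a
descriptor→activity mapping analytically, train an autoencoder so that
molecules become points z in a continuous space, then optimize a scoring
function S(z) directly in that space and decode the optima.

## The models

Four autoencoder variants share a convolutional encoder (three 1-d
convolutions + two dense layers, SELU activations) and a recurrent decoder
(dense latent projection + three GRU layers emitting a token distribution
at each of L positions):

- **NoTeacher VAE** — the encoder outputs a diagonal Gaussian posterior
  q(z|X) = N(μ(X), σ²(X)); training minimizes the negative ELBO

      L = E_q[−log p_θ(X|z)] + w·D_KL(q_φ(z|X) ‖ N(0, I)),

  with the last decoder layer conditioned only on the previous layer.
- **Teacher VAE** — same objective; the last decoder layer additionally
  receives the previous token (target token in training, sampled token in
  generation — *teacher forcing*).
- **Gauss AAE / Uniform AAE** — the encoder is deterministic and a
  discriminator D shapes the latent distribution toward a prior p(z) via a
  three-step per-batch loop: (1) encoder+decoder minimize reconstruction,
  (2) D minimizes −(log D(z′) + log(1 − D(z))) on prior draws z′ vs encoder
  outputs z, (3) the encoder minimizes −log D(z).

Decoding a latent point samples the token distributions (500 sequences by
default); the most frequently sampled *valid* SMILES is the consensus
output.  The search objective is S(z) = mean P_active over the predicted
actives among the decoded compounds (fallback: mean over all valid
decodes; 0 when nothing decodes), with P_active from an ECFP6 + RBF-SVM
classifier, and structures containing rings of more than eight atoms
filtered out.  Optimization is GP + expected improvement (100 random
starting points, then 500 guided iterations by default).

The networks run on a small numpy reverse-mode autodiff engine included in
the package (`aemol._autodiff`) — no deep-learning framework required.

## Worked example

```python
import numpy as np
from aemol import SmilesVAE, make_fixture_corpus, corpus_metrics

corpus = make_fixture_corpus(50, seed=7, complexity="full")
model = SmilesVAE(
    latent_dim=16, max_length=40, teacher_forcing=True,
    conv_channels=(8, 8, 8), kernel_size=5, dense_dim=96, gru_dim=56,
    kl_weight=0.02, kl_anneal_epochs=100, batch_size=50,
    learning_rate=3e-3, n_epochs=700, stop_accuracy=0.9995,
    eval_every=20, random_state=0,
).fit(corpus)

print(corpus_metrics(model, corpus, mode="training"))
print(corpus_metrics(model, corpus, mode="generation", n_samples=100,
                     rng=np.random.default_rng(11)))

z = model.transform(corpus[:1])           # latent point of the first molecule
print(corpus[0], "->", model.inverse_transform(z, n_samples=100)[0])
```

prints (about a minute on one CPU):

```
{'mode': 'training', 'mean_char_accuracy_pct': 99.95, 'n_molecules': 50}
{'mode': 'generation', 'mean_char_accuracy_pct': 92.676, 'valid_smiles_pct': 62.54, 'consensus_char_accuracy_pct': 99.5, 'consensus_exact_pct': 96.0, 'n_molecules': 50, 'n_samples_per_molecule': 100}
CCCC(C)OCCc1cccc2ccccc12 -> CCCC(C)OCCc1cccc2ccccc12
```

Reading: after overfitting a 50-molecule corpus the decoder reproduces
99.95 % of characters under teacher-forced decoding; free-running
generation is noisier per sample (92.7 % of characters, 62.5 % of samples
are valid molecules), but consensus over 100 samples recovers 48 of the 50
molecules exactly — including the round trip of the naphthalene ether
shown.

A command-line interface mirrors the library (`aemol fixtures`, `prepare`,
`split`, `train`, `generate`, `metrics`, `train-qsar`, `score`, `search`,
`probe`); every command takes `--seed` and file paths, so full runs are
scriptable end to end.

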