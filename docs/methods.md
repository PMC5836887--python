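# Methods

## Overview

`aemol` maps molecules, written as SMILES strings, into a continuous latent
space with a generative autoencoder, decodes latent points back into
molecules by repeated sampling, and searches the latent space for molecules
that score well under a fingerprint-based activity model.  Four autoencoder
variants are provided: a variational autoencoder with and without teacher
forcing, and an adversarial autoencoder whose latent distribution is shaped
toward either a standard Gaussian or a per-coordinate uniform prior.

## Sequence representation

SMILES are canonicalized with RDKit and stereochemistry is removed.  Strings
are tokenized per character except the two-character halogen atoms `Cl` and
`Br`, which are single tokens; the vocabulary is derived from the training
corpus (pad token first, remaining tokens in lexicographic order, so the
mapping is corpus-order independent).  Sequences are padded with spaces to a
fixed length (default 120 tokens) and one-hot encoded.  The pad character
doubles as the terminator: decoding cuts at the first pad.  There is no
start token; the decoder's "previous token" input at the first position is
the pad symbol.

## Networks

The encoder applies three 1-d convolutions along the sequence (SELU
activations) followed by two fully connected layers.  For the VAE the final
layer parameterizes a diagonal Gaussian posterior q(z|X) = N(μ(X), σ²(X));
for the AAE it outputs the latent point directly.  The decoder projects z
through a fully connected layer; the projection initializes the state of a
three-layer GRU stack and is fed as the first layer's input at every step.
With teacher forcing the last GRU layer's input is the concatenation of the
previous layer's output and the previous token — the target token during
training, the sampled token during generation.  Without teacher forcing the
last layer sees only the previous layer's output in both modes, so the
output distribution is a function of z alone.

All networks are implemented in this package on a small reverse-mode
automatic-differentiation engine over numpy (`aemol._autodiff`), with
parameters in float32 and Adam as the optimizer.  Gradient correctness is
verified against central differences in the test suite.

## Losses

The VAE minimizes the negative evidence lower bound

    L = E_q[-log p(X|z)] + w · D_KL(q(z|X) ‖ N(0, I)),

where the reconstruction term sums the token negative log-likelihood over
*all* positions up to the padded length (pad positions included — the
reconstruction metric is defined position-to-position over the full padded
string, so the objective matches the metric), and the KL term has the closed
form −½ Σᵢ (1 + log σᵢ² − μᵢ² − σᵢ²).  The weight w is annealed linearly
from 0 to its final value (`kl_weight`) over `kl_anneal_epochs`; unannealed
sequence VAEs are prone to posterior collapse.  Setting w = 1 recovers the
plain ELBO.

The AAE replaces the KL term with an adversarial game.  Each mini-batch runs
three sequential updates:

1. encoder + decoder minimize the reconstruction loss E[-log p(X|z)];
2. a discriminator D (three dense layers: affine, affine + SELU,
   affine + sigmoid) minimizes −(log D(z′) + log(1 − D(z))) where z′ are
   fresh prior draws and z are (detached) encoder outputs;
3. the encoder minimizes −log D(z), i.e. is trained to fool D.

Probabilities are clamped to [1e−7, 1 − 1e−7] before logs.  The AAE decoder
always uses teacher forcing; configuration validation rejects attempts to
disable it.  The uniform prior's bounds default to [−1, 1] per coordinate
(an open parameter, configurable).  A separate adversarial learning rate
(`adv_learning_rate`, defaulting to the reconstruction rate) lets the
regularization pressure be weakened when the goal is maximal reconstruction
on a tiny corpus rather than tight prior matching.

## Generation and metrics

A latent point is decoded by sampling the output distribution at every
position (temperature 1, via the Gumbel-argmax identity), 500 times by
default.  Each sampled index sequence becomes a string; validity is checked
with RDKit (the empty molecule counts as invalid).  The consensus output is
the most frequently sampled *valid* string, ties broken lexicographically;
a latent point with no valid samples has no consensus.

Reconstruction metrics: *training mode* scores argmax predictions under the
training-time input regime, evaluated at the posterior mean (VAE) or the
encoder output (AAE) so the number is deterministic; *generation mode*
reports the mean per-sample character accuracy (percentage of agreeing
positions after padding both strings), the percentage of valid SMILES over
all reconstruction attempts (each sample counts), and consensus-level
accuracy and exact-identity rates separately.

## Activity model and score

Activity is modelled by an SVM with Gaussian kernel over
extended-connectivity fingerprints of diameter 6 (Morgan radius 3), folded
to 2048 bits (configurable; the bit length is an open parameter).  C and γ
are chosen by stratified cross-validated grid search on AUROC, with
balanced class weights for imbalanced tables; the cross-validated AUROC of
the final model is stored as `cv_auroc_`.  The decision threshold for
"active" is P_active > 0.5.

The search objective at a latent point z is

    S(z) = mean P_active over predicted actives among the sampled valid
           compounds, or the mean over all sampled valid compounds when
           none is predicted active; 0 when nothing valid decodes.

Each distinct compound counts once by default (`unique=True`; sampling-
frequency weighting is available).  Structures containing any
smallest-set-of-smallest-rings ring with more than eight atoms are removed
before scoring: unconstrained latent search otherwise drifts toward large
macrocycles of low synthetic feasibility.  An eight-membered ring is kept;
a nine-membered ring is removed.

## Latent search

Bayesian optimization maximizes S(z) over a box: the prior's support for
uniform-prior models, [−4, 4] per coordinate otherwise (> 99.99 % of the
Gaussian mass).  The surrogate is a Gaussian process with a squared-
exponential kernel (single length scale, constant amplitude, jitter 1e−6,
hyperparameters by marginal likelihood, via scikit-learn).  The expected
improvement EI(x) = (μ−f*)Φ(u) + σφ(u), u = (μ−f*)/σ, is maximized by
scoring 512 random candidates and refining the best three with L-BFGS-B.
The default budget is 100 random starting points followed by 500 guided
iterations; repeated searches restart independently.  An objective failure
at a point records score 0 and the search continues, mirroring the
treatment of non-decodable latent points.

The similarity probe checks whether the latent space preserves the chemical
similarity principle: for distances d = 0 … 8 in steps of 0.1, points are
drawn uniformly on the sphere of radius d around the query's latent vector
(10 points per bin, 500 decodes per point = 5000 reconstruction attempts
per bin at the defaults), and the median ECFP6 Tanimoto similarity of the
valid decodes to the query plus the valid fraction are recorded per bin.

## Synthetic fixture corpora

`make_fixture_corpus` assembles molecules from curated fragments (branched
chains, aliphatic rings, aromatic scaffolds with substituents including Cl
and Br), canonicalizes each candidate and keeps only unique, valid results.
The `full` tier additionally guarantees ≥ 10 heavy atoms and a steady
supply of halogenated molecules, so the corpus passes the default corpus
filters and exercises every tokenizer path.  It emulates the *structural
variety* of a real training corpus — rings, branches, aromaticity,
two-character tokens — not its scale, chemical diversity, or property
distributions.  Tests passing on these corpora demonstrate that the
machinery is correct; they say nothing about reconstruction rates or latent
smoothness at the scale of millions of molecules, which require wide
networks and long training.

## Study conditions used by the tests and the acceptance script

Production-scale defaults (56-d latent, 120-token sequences, batch 500, learning
rate 3.1e−4, Adam) are the estimator defaults.  The test suite and the
acceptance script run desk-scale conditions chosen once: 50-molecule `full`
corpus, 40-token sequences, 16-d latent, GRU width 56, learning rate 3e−3,
full-corpus batches, training stopped once teacher-forced character
accuracy reaches 99.95 % (cap 700–1600 epochs depending on variant).  Under
these conditions every variant exceeds 99 % training-mode character
accuracy in roughly one to two minutes on one CPU, and the teacher-forced
variants recover ≥ 90 % of the corpus exactly via 100-sample consensus
decoding.

Adversarial prior matching is assessed on a 200-molecule corpus with an
8-d latent space (400 epochs Gaussian, 500 uniform, learning rate 1e−3).
Tolerances: pooled encoder-output mean within ±0.25 of the prior mean and
pooled variance within [0.6, 1.5] × the prior variance; these combine
Monte-Carlo error at ~1600 pooled coordinate values with the residual slack
of a finite adversarial game, and are far looser than what large-scale
training achieves.  Held-out discriminator accuracy must lie in [0.4, 0.6].

## Numerical choices and degenerate inputs

- Token sampling uses the Gumbel-argmax identity with a fixed per-run
  generator; all stochastic entry points take explicit seeds or generators.
- σ = 0 in the reparameterization returns the mean exactly; EI at σ = 0 is
  max(μ − f*, 0).
- Consensus ties break lexicographically; an all-pad sample decodes to the
  empty string and is invalid.
- The empty SMILES string is invalid; empty probability sets score 0.
- Two empty fingerprints have Tanimoto similarity 1 by convention.
- Sigmoid inputs are clipped at ±60 to avoid overflow in float32.

## Known limitations

- Networks are CPU-bound numpy; corpus-scale training (10⁶ molecules,
  120-token sequences, 56-d latent) is out of reach here and the published
  large-scale reconstruction/validity rates are not reproduced.
- The decoder conditions every step on the projected latent vector; an
  architecture that uses z only to initialize the recurrent state is not
  provided.
- Bracket atoms (e.g. `[nH]`) are tokenized per character, matching a
  corpus-derived single-character alphabet; SELFIES/InChI inputs and
  stereochemistry-aware encoding are out of scope.
- The similarity probe draws points on exact spheres; other definitions of
  "random points at distance d" (e.g. Gaussian offsets of given norm in a
  subspace) are not implemented.
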