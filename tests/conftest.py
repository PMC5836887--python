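"""Shared fixtures: fixture corpora and desk-scale trained models.

Training-dependent tests share session-scoped models overfit on a small
synthetic corpus (50 molecules, 40-token sequences, 16-d latent space).
These sizes are the package's desk-scale study conditions: small enough to
train each autoencoder variant on one CPU in about a minute, rich enough
(rings, branches, aromatics, Cl/Br) to exercise every codec and decoder
path.
"""

import numpy as np
import pytest

from aemol.aae import SmilesAAE
from aemol.codec import build_vocabulary
from aemol.data import make_fixture_corpus
from aemol.generate import corpus_metrics
from aemol.qsar import ActivityClassifier
from aemol.vae import SmilesVAE

# network widths shared by every overfit model
OVERFIT_NET = dict(
    max_length=40, conv_channels=(8, 8, 8), kernel_size=5, dense_dim=96,
    gru_dim=56, latent_dim=16, batch_size=50,
)


@pytest.fixture(scope="session")
def fixture_corpus():
    return make_fixture_corpus(50, seed=7, complexity="full")


@pytest.fixture(scope="session")
def vocab(fixture_corpus):
    return build_vocabulary(fixture_corpus, max_length=40)


@pytest.fixture(scope="session")
def teacher_vae(fixture_corpus):
    return SmilesVAE(
        teacher_forcing=True, kl_weight=0.02, kl_anneal_epochs=100,
        learning_rate=3e-3, n_epochs=700, stop_accuracy=0.9995,
        eval_every=20, random_state=0, **OVERFIT_NET,
    ).fit(fixture_corpus)


@pytest.fixture(scope="session")
def noteacher_vae(fixture_corpus):
    return SmilesVAE(
        teacher_forcing=False, kl_weight=0.02, kl_anneal_epochs=100,
        learning_rate=3e-3, n_epochs=1600, stop_accuracy=0.995,
        eval_every=25, random_state=0, **OVERFIT_NET,
    ).fit(fixture_corpus)


@pytest.fixture(scope="session")
def aae_gauss(fixture_corpus):
    return SmilesAAE(
        prior="gaussian", adv_learning_rate=3e-4, disc_hidden=(64, 64),
        learning_rate=3e-3, n_epochs=900, stop_accuracy=0.9997,
        eval_every=20, random_state=0, **OVERFIT_NET,
    ).fit(fixture_corpus)


@pytest.fixture(scope="session")
def aae_uniform(fixture_corpus):
    return SmilesAAE(
        prior="uniform", adv_learning_rate=3e-4, disc_hidden=(64, 64),
        learning_rate=3e-3, n_epochs=900, stop_accuracy=0.9997,
        eval_every=20, random_state=0, **OVERFIT_NET,
    ).fit(fixture_corpus)


@pytest.fixture(scope="session")
def overfit_models(teacher_vae, noteacher_vae, aae_gauss, aae_uniform):
    return {
        "vae_teacher": teacher_vae,
        "vae_noteacher": noteacher_vae,
        "aae_gauss": aae_gauss,
        "aae_uniform": aae_uniform,
    }


@pytest.fixture(scope="session")
def generation_metrics(overfit_models, fixture_corpus):
    """Generation-mode reconstruction metrics per variant (100 samples/mol)."""
    return {
        name: corpus_metrics(model, fixture_corpus, mode="generation",
                             n_samples=100, rng=np.random.default_rng(11))
        for name, model in overfit_models.items()
    }


@pytest.fixture(scope="session")
def prior_corpus():
    # larger corpus for latent-moment estimation in the adversarial models
    return make_fixture_corpus(200, seed=13, complexity="full")


@pytest.fixture(scope="session")
def aae_prior_models(prior_corpus):
    """AAEs trained for prior matching (narrower 8-d latent, longer run)."""
    models = {}
    for prior, n_epochs in (("gaussian", 400), ("uniform", 500)):
        models[prior] = SmilesAAE(
            latent_dim=8, max_length=40, prior=prior, conv_channels=(8, 8, 8),
            kernel_size=5, dense_dim=64, gru_dim=40, disc_hidden=(48, 48),
            batch_size=50, learning_rate=1e-3, n_epochs=n_epochs,
            random_state=0,
        ).fit(prior_corpus)
    return models


@pytest.fixture(scope="session")
def qsar_data():
    """Two structurally disjoint families: aromatics (active) vs chains."""
    actives = make_fixture_corpus(60, seed=31, complexity="full")
    inactives = make_fixture_corpus(60, seed=32, complexity="simple")
    return actives, inactives


@pytest.fixture(scope="session")
def activity_model(qsar_data):
    actives, inactives = qsar_data
    clf = ActivityClassifier(cv=3, random_state=0)
    return clf.fit(actives + inactives, [1] * len(actives) + [0] * len(inactives))
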