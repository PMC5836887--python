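"""Corpus preparation, splitting, the training driver and fixture corpora.

Corpus preparation applies the standard cleanup used for training the
autoencoders: canonicalize with RDKit, strip stereochemistry, drop molecules
with fewer than 10 heavy atoms or more than ``max_tokens`` tokens, remove an
exclusion list (e.g. the known actives of the search target, so generated
hits are genuinely novel), and deduplicate on the canonical form.

``make_fixture_corpus`` assembles small, chemically valid molecules from a
curated fragment set so that every codec path (ring closures, branches,
aromatic atoms, two-character halogens) is exercised without any external
download.  It is first-class, deterministic, tested code — not a stand-in
for real data quality, only for its structural variety.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from . import codec
from .aae import SmilesAAE
from .vae import SmilesVAE

VARIANTS = ("vae_noteacher", "vae_teacher", "aae_gauss", "aae_uniform")


@dataclass
class CorpusSpec:
    """Filtering rules applied by :func:`prepare_corpus`."""

    min_heavy_atoms: int = 10
    max_tokens: int = 120
    exclusion_list: set = field(default_factory=set)
    strip_stereo: bool = True

    def __post_init__(self):
        if self.min_heavy_atoms < 1 or self.max_tokens < 1:
            raise ValueError("min_heavy_atoms and max_tokens must be >= 1")


def prepare_corpus(raw: list[str], spec: CorpusSpec | None = None
                   ) -> tuple[list[str], dict]:
    """Canonicalize and filter a raw SMILES list.

    Returns the surviving canonical SMILES (input order of first occurrence)
    and a report counting removals per rule.  Filters are applied in order:
    parseability, heavy-atom count, token count, exclusion list, duplicates.
    """
    spec = spec or CorpusSpec()
    if not raw:
        raise ValueError("empty input corpus")
    excluded = {
        codec.canonicalize(s, strip_stereo=spec.strip_stereo)
        for s in spec.exclusion_list
    }
    report = {
        "n_input": len(raw),
        "n_unparseable": 0,
        "n_too_few_heavy_atoms": 0,
        "n_too_long": 0,
        "n_excluded": 0,
        "n_duplicate": 0,
    }
    seen: set[str] = set()
    out: list[str] = []
    for s in raw:
        try:
            canon = codec.canonicalize(s, strip_stereo=spec.strip_stereo)
        except codec.SmilesParseError:
            report["n_unparseable"] += 1
            continue
        mol = Chem.MolFromSmiles(canon)
        if mol.GetNumHeavyAtoms() < spec.min_heavy_atoms:
            report["n_too_few_heavy_atoms"] += 1
            continue
        if len(codec.tokenize(canon)) > spec.max_tokens:
            report["n_too_long"] += 1
            continue
        if canon in excluded:
            report["n_excluded"] += 1
            continue
        if canon in seen:
            report["n_duplicate"] += 1
            continue
        seen.add(canon)
        out.append(canon)
    if not out:
        raise ValueError("no molecules survived corpus preparation")
    report["n_output"] = len(out)
    return out, report


def split_corpus(corpus: list[str], validation_fraction: float,
                 seed: int = 0) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive, seed-reproducible train/validation split."""
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n_val = round(len(corpus) * validation_fraction)
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(corpus) if i not in val_idx]
    val = [s for i, s in enumerate(corpus) if i in val_idx]
    return train, val


# -- fixture corpus ----------------------------------------------------------

_CHAIN_UNITS = ["C", "C", "CC", "O", "N", "C(C)", "C(=O)"]

_RING_SCAFFOLDS = [
    "C1CCCCC1", "C1CCCC1", "C1CCOCC1", "C1CCNCC1", "C1CCCCCC1",
]

_AROMATIC_TEMPLATES = [
    "c1ccc({sub})cc1", "c1ccnc({sub})c1", "c1ccc2ccccc2c1", "c1cc({sub})ccc1{sub2}",
    "c1ccc({sub})nc1", "Cc1ccc({sub})cc1", "c1cc({sub})cs1", "c1cc({sub})c[nH]1",
]

_SUBSTITUENTS = [
    "C", "CC", "CCC", "O", "OC", "N", "N(C)C", "C(=O)O", "C(=O)OC",
    "C(=O)N", "F", "Cl", "Br", "C#N", "CCO", "C(F)(F)F",
]

_HALOGEN_SUBS = ["Cl", "Br"]


def _random_chain(rng: np.random.Generator, n_units: int) -> str:
    return "C" + "".join(rng.choice(_CHAIN_UNITS) for _ in range(n_units))


def _candidate(rng: np.random.Generator, complexity: str, force_halogen: bool) -> str:
    if complexity == "simple":
        return _random_chain(rng, int(rng.integers(3, 9)))
    if complexity == "ringed" and rng.random() < 0.6:
        scaffold = str(rng.choice(_RING_SCAFFOLDS))
        return scaffold + _random_chain(rng, int(rng.integers(1, 5)))
    if complexity == "full":
        template = str(rng.choice(_AROMATIC_TEMPLATES))
        sub_pool = _HALOGEN_SUBS if force_halogen else _SUBSTITUENTS
        filled = template.replace("{sub}", str(rng.choice(sub_pool)))
        filled = filled.replace("{sub2}", str(rng.choice(_SUBSTITUENTS)))
        # pad with an aliphatic tail until the 10-heavy-atom floor is safe
        return filled + _random_chain(rng, int(rng.integers(2, 6)))
    return _random_chain(rng, int(rng.integers(3, 9)))


def make_fixture_corpus(n: int, seed: int = 0, complexity: str = "full"
                        ) -> list[str]:
    """Deterministic list of ``n`` unique, valid, canonical SMILES.

    Tiers: ``simple`` (chains/branches), ``ringed`` (adds aliphatic rings),
    ``full`` (adds aromatics and guarantees Cl/Br molecules and >= 10 heavy
    atoms, so the corpus survives :func:`prepare_corpus` at its defaults).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if complexity not in ("simple", "ringed", "full"):
        raise ValueError(f"unknown complexity tier {complexity!r}")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("fixture assembly failed to reach n molecules")
        force_halogen = complexity == "full" and (len(out) % 5 == 0)
        raw = _candidate(rng, complexity, force_halogen)
        try:
            canon = codec.canonicalize(raw)
        except codec.SmilesParseError:
            continue
        if not codec.is_valid_smiles(canon) or canon in seen:
            continue
        mol = Chem.MolFromSmiles(canon)
        if complexity == "full" and mol.GetNumHeavyAtoms() < 10:
            continue
        if len(codec.tokenize(canon)) > 120:
            continue
        seen.add(canon)
        out.append(canon)
    return out


@dataclass
class TrainingConfig:
    """Optimizer schedule for the training driver (production-scale defaults)."""

    batch_size: int = 500
    learning_rate: float = 3.1e-4
    latent_dim: int = 56
    n_epochs: int = 200
    stop_accuracy: float | None = None
    eval_every: int = 10

    def __post_init__(self):
        if min(self.batch_size, self.latent_dim, self.n_epochs) <= 0:
            raise ValueError("batch_size, latent_dim and n_epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def train_model(corpus: list[str], variant: str,
                training: TrainingConfig | None = None, seed: int = 0,
                **model_kwargs):
    """Fit one of the four autoencoder variants on a prepared corpus.

    ``variant``: ``vae_noteacher`` | ``vae_teacher`` | ``aae_gauss`` |
    ``aae_uniform``.  Extra keyword arguments override network widths
    (``gru_dim``, ``max_length``, ...).  Returns the fitted estimator with a
    per-epoch ``history_``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    training = training or TrainingConfig()
    common = dict(
        latent_dim=training.latent_dim,
        batch_size=training.batch_size,
        learning_rate=training.learning_rate,
        n_epochs=training.n_epochs,
        stop_accuracy=training.stop_accuracy,
        eval_every=training.eval_every,
        random_state=seed,
    )
    common.update(model_kwargs)
    if variant == "vae_noteacher":
        model = SmilesVAE(teacher_forcing=False, **common)
    elif variant == "vae_teacher":
        model = SmilesVAE(teacher_forcing=True, **common)
    elif variant == "aae_gauss":
        model = SmilesAAE(prior="gaussian", **common)
    else:
        model = SmilesAAE(prior="uniform", **common)
    return model.fit(corpus)
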