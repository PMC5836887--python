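"""Generation-mode decoding, consensus selection and reconstruction metrics.

A latent point is decoded by sampling the decoder's output distribution many
times (500 by default).  Each sampled index sequence is turned back into a
string and checked for chemical validity; the most frequently sampled valid
string is the latent point's consensus output.  Ties are broken
lexicographically so results are reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import codec


@dataclass
class GenerationReport:
    """Outcome of repeatedly decoding one latent point."""

    latent: np.ndarray
    samples: list[str]
    valid_fraction: float
    consensus_smiles: str | None
    frequency_table: dict[str, int] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def select_consensus(samples: list[str]) -> tuple[str | None, dict[str, int]]:
    """Most frequent valid string (lexicographic tie-break) and counts."""
    table = dict(Counter(samples))
    valid = [(n, s) for s, n in table.items() if codec.is_valid_smiles(s)]
    if not valid:
        return None, table
    best_n = max(n for n, _ in valid)
    consensus = min(s for n, s in valid if n == best_n)
    return consensus, table


def generate(model, z: np.ndarray, n_samples: int = 500,
             rng: np.random.Generator | None = None) -> GenerationReport:
    """Sample ``n_samples`` sequences at latent point ``z`` and summarize."""
    rng = rng or np.random.default_rng(0)
    z = np.asarray(z, dtype=np.float64).reshape(1, -1)
    tokens = model.sample_tokens(z, n_samples, rng)
    samples = [codec.decode_indices(row, model.vocab_) for row in tokens]
    n_valid = sum(codec.is_valid_smiles(s) for s in samples)
    consensus, table = select_consensus(samples)
    return GenerationReport(
        latent=z.ravel(),
        samples=samples,
        valid_fraction=n_valid / n_samples,
        consensus_smiles=consensus,
        frequency_table=table,
    )


def character_reconstruction_accuracy(predicted: str, target: str,
                                      max_length: int = 120) -> float:
    """Percentage of positions that agree after padding both to max_length."""
    p = predicted[:max_length].ljust(max_length, codec.PAD_TOKEN)
    t = target[:max_length].ljust(max_length, codec.PAD_TOKEN)
    matches = sum(a == b for a, b in zip(p, t))
    return 100.0 * matches / max_length


def corpus_metrics(model, corpus: list[str], mode: str = "training",
                   n_samples: int = 500,
                   rng: np.random.Generator | None = None) -> dict:
    """Reconstruction metrics over a corpus.

    ``training`` mode scores argmax predictions under the training-time input
    regime (teacher forcing when the model uses it).  ``generation`` mode
    encodes each molecule, samples ``n_samples`` sequences from its latent
    point and reports the mean per-sample character accuracy, the percentage
    of valid samples over all reconstruction attempts, and consensus-level
    accuracy/identity.
    """
    rng = rng or np.random.default_rng(0)
    L = model.vocab_.max_length
    if mode == "training":
        pred_idx = model.predict_train_tokens(corpus)
        accs = [
            character_reconstruction_accuracy(
                codec.decode_indices(row, model.vocab_), s, L
            )
            for row, s in zip(pred_idx, corpus)
        ]
        return {
            "mode": "training",
            "mean_char_accuracy_pct": float(np.mean(accs)),
            "n_molecules": len(corpus),
        }
    if mode != "generation":
        raise ValueError(f"unknown mode {mode!r}")
    Z = model.latent_of(corpus)
    sample_accs: list[float] = []
    n_valid_attempts = 0
    n_attempts = 0
    consensus_accs: list[float] = []
    n_consensus_exact = 0
    for s, z in zip(corpus, Z):
        rep = generate(model, z, n_samples=n_samples, rng=rng)
        sample_accs.extend(
            character_reconstruction_accuracy(p, s, L) for p in rep.samples
        )
        n_valid_attempts += round(rep.valid_fraction * rep.n_samples)
        n_attempts += rep.n_samples
        cons = rep.consensus_smiles or ""
        consensus_accs.append(character_reconstruction_accuracy(cons, s, L))
        n_consensus_exact += int(cons == s)
    return {
        "mode": "generation",
        "mean_char_accuracy_pct": float(np.mean(sample_accs)),
        "valid_smiles_pct": 100.0 * n_valid_attempts / n_attempts,
        "consensus_char_accuracy_pct": float(np.mean(consensus_accs)),
        "consensus_exact_pct": 100.0 * n_consensus_exact / len(corpus),
        "n_molecules": len(corpus),
        "n_samples_per_molecule": n_samples,
    }
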