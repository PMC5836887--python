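"""SMILES canonicalization, tokenization and one-hot sequence encoding.

SMILES strings are tokenized character by character, except for the
two-character halogen atoms ``Cl`` and ``Br`` which form single tokens.
Sequences are padded with spaces to a fixed length; the pad character doubles
as the terminator (decoding stops at the first pad).  RDKit provides
canonicalization, stereochemistry stripping and validity checking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

PAD_TOKEN = " "
TWO_CHAR_TOKENS = ("Cl", "Br")


class SmilesParseError(ValueError):
    """Raised when a string cannot be parsed as a molecule."""


class TokenizationError(ValueError):
    """Raised when a string contains a token outside the vocabulary."""


class SequenceLengthError(ValueError):
    """Raised when a tokenized SMILES exceeds the maximum sequence length."""


def canonicalize(smiles: str, strip_stereo: bool = True) -> str:
    """Return the canonical SMILES, optionally removing stereochemistry.

    Idempotent: canonicalizing a canonical string returns it unchanged.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    if strip_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def is_valid_smiles(smiles: str) -> bool:
    """True iff the string parses to a non-empty molecule."""
    if not smiles:
        return False
    mol = Chem.MolFromSmiles(smiles)
    return mol is not None and mol.GetNumAtoms() > 0


def tokenize(smiles: str, vocab: "TokenVocabulary | None" = None) -> list[str]:
    """Split a SMILES string into tokens; ``Cl``/``Br`` are never split.

    With a vocabulary, unknown tokens raise :class:`TokenizationError`
    reporting the position and offending fragment.
    """
    tokens: list[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        if smiles[i : i + 2] in TWO_CHAR_TOKENS:
            tok = smiles[i : i + 2]
        else:
            tok = smiles[i]
        if vocab is not None and tok not in vocab.index_of:
            raise TokenizationError(
                f"unknown token {tok!r} at position {i} in {smiles!r}"
            )
        tokens.append(tok)
        i += len(tok)
    return tokens


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token alphabet with the pad/terminator at index 0."""

    tokens: tuple[str, ...]
    max_length: int = 120
    pad_token: str = PAD_TOKEN
    index_of: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        if self.pad_token not in self.tokens:
            raise ValueError("pad token missing from vocabulary")
        object.__setattr__(
            self, "index_of", {t: i for i, t in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return self.index_of[self.pad_token]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"tokens": list(self.tokens), "max_length": self.max_length})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TokenVocabulary":
        obj = json.loads(Path(path).read_text())
        return cls(tokens=tuple(obj["tokens"]), max_length=int(obj["max_length"]))


def build_vocabulary(corpus: list[str], max_length: int = 120) -> TokenVocabulary:
    """Derive the token alphabet from a corpus.

    The pad token comes first, the observed tokens follow in lexicographic
    order, so the result is independent of corpus ordering.
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    seen: set[str] = set()
    for s in corpus:
        seen.update(tokenize(s))
    seen.discard(PAD_TOKEN)
    return TokenVocabulary(tokens=(PAD_TOKEN, *sorted(seen)), max_length=max_length)


@dataclass
class OneHotSequence:
    """A tokenized, padded SMILES as index vector plus one-hot matrix."""

    indices: np.ndarray  # (max_length,) int
    onehot: np.ndarray  # (max_length, |tokens|) uint8
    source_smiles: str


def encode_indices(smiles: str, vocab: TokenVocabulary) -> np.ndarray:
    toks = tokenize(smiles, vocab)
    if len(toks) > vocab.max_length:
        raise SequenceLengthError(
            f"{len(toks)} tokens exceed max_length={vocab.max_length}: {smiles!r}"
        )
    idx = np.full(vocab.max_length, vocab.pad_index, dtype=np.int64)
    for i, t in enumerate(toks):
        idx[i] = vocab.index_of[t]
    return idx


def encode(smiles: str, vocab: TokenVocabulary) -> OneHotSequence:
    """Tokenize, pad to ``max_length`` and one-hot encode a SMILES string."""
    idx = encode_indices(smiles, vocab)
    onehot = np.eye(len(vocab), dtype=np.uint8)[idx]
    return OneHotSequence(indices=idx, onehot=onehot, source_smiles=smiles)


def encode_corpus(corpus: list[str], vocab: TokenVocabulary) -> np.ndarray:
    """Index matrix (n_molecules, max_length) for a whole corpus."""
    return np.stack([encode_indices(s, vocab) for s in corpus])


def indices_to_onehot(indices: np.ndarray, n_tokens: int) -> np.ndarray:
    return np.eye(n_tokens, dtype=np.float32)[indices]


def decode_indices(indices: np.ndarray | list[int], vocab: TokenVocabulary) -> str:
    """Map an index sequence back to a string, stopping at the first pad.

    No validity checking is performed; syntactically broken strings are
    returned verbatim so that validity can be assessed separately.
    """
    out: list[str] = []
    for i in np.asarray(indices, dtype=np.int64):
        if i < 0 or i >= len(vocab):
            raise IndexError(f"token index {i} out of range for |V|={len(vocab)}")
        if i == vocab.pad_index:
            break
        out.append(vocab.tokens[i])
    return "".join(out)


def read_smiles_file(path: str | Path) -> list[str]:
    """Read SMILES one per line (or the ``smiles`` column of a CSV)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        import pandas as pd

        df = pd.read_csv(path)
        col = next(c for c in df.columns if c.lower() == "smiles")
        return df[col].astype(str).tolist()
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]
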