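"""SMILES <-> one-hot codec and the validity / realism predicates.

SMILES strings are tokenized at the character level (with an optional merge
list for two-character element symbols such as Cl and Br), mapped onto an
ordered alphabet, and encoded as fixed-length ``L x A`` one-hot matrices with
a pad token filling positions past the end of the string.  A *valid* string
is one RDKit can parse and sanitize; a *realistic* string is valid and longer
than a small character-length cutoff, a heuristic that excludes degenerate
decodings such as methane ``"C"``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

#: default pad token, guaranteed not to occur in any SMILES string
PAD_TOKEN = " "

#: two-character element symbols merged into single tokens by default
DEFAULT_MERGE_TOKENS = ("Cl", "Br")

#: a string is "realistic" when valid and strictly longer than this
REALISTIC_LENGTH_THRESHOLD = 5


class CodecError(ValueError):
    """Raised on tokenization / encoding contract violations."""


def tokenize(smiles: str, merge_tokens: Sequence[str] = DEFAULT_MERGE_TOKENS) -> list[str]:
    """Split a SMILES string into single-character tokens, merging the
    two-character element symbols in ``merge_tokens``."""
    tokens: list[str] = []
    i = 0
    while i < len(smiles):
        two = smiles[i : i + 2]
        if two in merge_tokens:
            tokens.append(two)
            i += 2
        else:
            tokens.append(smiles[i])
            i += 1
    return tokens


@dataclass(frozen=True)
class Alphabet:
    """Ordered token inventory of a SMILES corpus plus a pad token (last)."""

    characters: tuple[str, ...]
    pad_token: str = PAD_TOKEN
    merge_tokens: tuple[str, ...] = DEFAULT_MERGE_TOKENS

    def __post_init__(self) -> None:
        if len(set(self.characters)) != len(self.characters):
            raise CodecError("alphabet characters must be unique")
        if self.pad_token not in self.characters:
            raise CodecError("pad token must be a member of the alphabet")

    @property
    def size(self) -> int:
        return len(self.characters)

    @property
    def pad_index(self) -> int:
        return self.characters.index(self.pad_token)

    def index(self, token: str) -> int:
        try:
            return self.characters.index(token)
        except ValueError:
            raise CodecError(f"unknown character {token!r}") from None

    def to_json(self) -> str:
        return json.dumps(
            {
                "characters": list(self.characters),
                "pad_token": self.pad_token,
                "merge_tokens": list(self.merge_tokens),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Alphabet":
        d = json.loads(text)
        return cls(
            characters=tuple(d["characters"]),
            pad_token=d["pad_token"],
            merge_tokens=tuple(d.get("merge_tokens", DEFAULT_MERGE_TOKENS)),
        )


@dataclass(frozen=True)
class OneHotSequence:
    """An ``L x A`` one-hot matrix; rows past ``source_length`` are pad."""

    matrix: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2:
            raise CodecError("one-hot matrix must be 2-d")
        if not np.array_equal(m.sum(axis=1), np.ones(m.shape[0])):
            raise CodecError("every one-hot row must sum to exactly 1")
        if not np.isin(m, (0, 1)).all():
            raise CodecError("one-hot entries must be 0 or 1")
        if self.source_length > m.shape[0]:
            raise CodecError("source_length exceeds matrix length")


@dataclass(frozen=True)
class Molecule:
    """A SMILES string with its validity / realism flags."""

    smiles: str
    canonical_smiles: str | None
    valid: bool
    realistic: bool

    @classmethod
    def from_smiles(
        cls, smiles: str, length_threshold: int = REALISTIC_LENGTH_THRESHOLD
    ) -> "Molecule":
        mol = _parse(smiles)
        valid = mol is not None
        return cls(
            smiles=smiles,
            canonical_smiles=Chem.MolToSmiles(mol) if valid else None,
            valid=valid,
            realistic=valid and len(smiles) > length_threshold,
        )


def _parse(smiles: str):
    if not smiles:
        return None
    try:
        return Chem.MolFromSmiles(smiles)
    except Exception:
        return None


def is_valid(smiles: str) -> bool:
    """True iff the string parses to a sanitizable molecule under RDKit."""
    return _parse(smiles) is not None


def is_realistic(smiles: str, length_threshold: int = REALISTIC_LENGTH_THRESHOLD) -> bool:
    """True iff valid and raw character length strictly exceeds the cutoff."""
    return len(smiles) > length_threshold and is_valid(smiles)


def build_alphabet(
    corpus: Iterable[str],
    pad_token: str = PAD_TOKEN,
    merge_tokens: Sequence[str] = DEFAULT_MERGE_TOKENS,
) -> Alphabet:
    """Collect every token occurring in the corpus into a sorted alphabet,
    pad token last.  Deterministic for a given corpus."""
    tokens: set[str] = set()
    n = 0
    for s in corpus:
        n += 1
        tokens.update(tokenize(s, merge_tokens))
    if n == 0:
        raise CodecError("cannot build an alphabet from an empty corpus")
    if pad_token in tokens:
        raise CodecError(f"pad token {pad_token!r} occurs in the corpus")
    return Alphabet(
        characters=tuple(sorted(tokens)) + (pad_token,),
        pad_token=pad_token,
        merge_tokens=tuple(merge_tokens),
    )


def encode_onehot(smiles: str, alphabet: Alphabet, max_len: int) -> OneHotSequence:
    """Encode a SMILES string as an ``max_len x A`` one-hot matrix."""
    toks = tokenize(smiles, alphabet.merge_tokens)
    if len(toks) > max_len:
        raise CodecError(
            f"string of {len(toks)} tokens exceeds max length {max_len}: {smiles!r}"
        )
    mat = np.zeros((max_len, alphabet.size), dtype=np.int8)
    for i, t in enumerate(toks):
        mat[i, alphabet.index(t)] = 1
    mat[len(toks) :, alphabet.pad_index] = 1
    return OneHotSequence(matrix=mat, source_length=len(toks))


def decode_onehot(seq: OneHotSequence, alphabet: Alphabet) -> str:
    """Invert :func:`encode_onehot`; pad positions are dropped."""
    idx = np.argmax(seq.matrix, axis=1)
    chars = []
    for i in idx:
        if i == alphabet.pad_index:
            break
        chars.append(alphabet.characters[i])
    return "".join(chars)


def indices_to_string(indices: np.ndarray, alphabet: Alphabet) -> str:
    """Token indices -> string, truncating at the first pad/stop token."""
    chars = []
    for i in indices:
        if i == alphabet.pad_index:
            break
        chars.append(alphabet.characters[int(i)])
    return "".join(chars)


def read_corpus(path: str | Path, column: str | None = None) -> list[str]:
    """Read a SMILES corpus: plain text (one per line, '#' comments ignored)
    or, when ``column`` is given, a CSV file with that column."""
    path = Path(path)
    if column is not None:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or column not in reader.fieldnames:
                raise CodecError(f"column {column!r} not found in {path}")
            return [row[column].strip() for row in reader if row[column].strip()]
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_corpus(smiles: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(smiles) + "\n")
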