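"""Character-level SMILES one-hot codec.

A SMILES string is tokenized strictly per character (two-letter element
symbols such as ``Cl`` become two tokens) and mapped through a 1-based
character dictionary onto an ``L x M`` binary matrix: row *i* carries a
single 1 in the column of character *i*, rows past the end of the string
are all-zero padding.  A corpus of K strings becomes a ``K x L x M``
tensor.  Case is significant (aromatic ``c`` is not aliphatic ``C``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SmilesDictionary",
    "OutOfVocabularyError",
    "build_dictionary",
    "encode_smiles",
    "encode_batch",
    "decode_smiles",
]


class OutOfVocabularyError(KeyError):
    """A character in the input SMILES has no index in the dictionary."""


@dataclass(frozen=True)
class SmilesDictionary:
    """Injective map character -> 1-based index over a contiguous range.

    Indices must be exactly ``{1, ..., M}``; the alphabet excludes any
    padding symbol — padding is represented by all-zero rows instead.
    """

    char_to_index: Mapping[str, int]

    def __post_init__(self) -> None:
        indices = sorted(self.char_to_index.values())
        m = len(self.char_to_index)
        if indices != list(range(1, m + 1)):
            raise ValueError(
                f"dictionary indices must be exactly 1..{m}, got {indices}"
            )
        for ch in self.char_to_index:
            if len(ch) != 1:
                raise ValueError(f"dictionary keys must be single characters: {ch!r}")

    @property
    def size(self) -> int:
        """M, the alphabet size."""
        return len(self.char_to_index)

    def index(self, char: str) -> int:
        try:
            return self.char_to_index[char]
        except KeyError:
            raise OutOfVocabularyError(
                f"character {char!r} is not in the SMILES dictionary"
            ) from None

    @property
    def index_to_char(self) -> dict[int, str]:
        return {i: c for c, i in self.char_to_index.items()}

    def to_text(self, path: str | Path) -> None:
        """Persist as a two-column (character, index) tab-separated file."""
        lines = [
            f"{c}\t{i}"
            for c, i in sorted(self.char_to_index.items(), key=lambda kv: kv[1])
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_text(cls, path: str | Path) -> "SmilesDictionary":
        mapping: dict[str, int] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line:
                continue
            char, _, idx = line.partition("\t")
            mapping[char] = int(idx)
        return cls(mapping)


def build_dictionary(smiles_list: Sequence[str]) -> SmilesDictionary:
    """Build the character dictionary for a SMILES corpus.

    Characters are indexed 1..M in descending corpus frequency; ties are
    broken by first occurrence in the corpus.  An explicit user-supplied
    mapping can always be passed to :class:`SmilesDictionary` directly
    when a fixed published ordering must be reproduced.
    """
    if not smiles_list:
        raise ValueError("cannot build a dictionary from an empty corpus")
    counts: Counter[str] = Counter()
    first_seen: dict[str, int] = {}
    pos = 0
    for s in smiles_list:
        if not s:
            raise ValueError("corpus contains an empty SMILES string")
        for ch in s:
            counts[ch] += 1
            if ch not in first_seen:
                first_seen[ch] = pos
            pos += 1
    ordered = sorted(counts, key=lambda c: (-counts[c], first_seen[c]))
    return SmilesDictionary({c: i + 1 for i, c in enumerate(ordered)})


def encode_smiles(
    smiles: str, dictionary: SmilesDictionary, max_length: int
) -> np.ndarray:
    """One-hot encode a single SMILES string into an ``L x M`` binary matrix."""
    if len(smiles) > max_length:
        raise ValueError(
            f"SMILES of length {len(smiles)} exceeds max_length={max_length}"
        )
    out = np.zeros((max_length, dictionary.size), dtype=np.uint8)
    for row, ch in enumerate(smiles):
        out[row, dictionary.index(ch) - 1] = 1
    return out


@dataclass(frozen=True)
class EncodedSmilesTensor:
    """``K x L x M`` one-hot tensor plus the dictionary that produced it."""

    data: np.ndarray
    dictionary: SmilesDictionary

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("encoded tensor must be 3-dimensional (K, L, M)")
        if self.data.shape[2] != self.dictionary.size:
            raise ValueError("tensor depth does not match dictionary size")

    @property
    def n_chemicals(self) -> int:
        return self.data.shape[0]

    @property
    def max_length(self) -> int:
        return self.data.shape[1]

    @property
    def alphabet_size(self) -> int:
        return self.data.shape[2]


def encode_batch(
    smiles_list: Sequence[str],
    dictionary: SmilesDictionary,
    max_length: int | None = None,
) -> EncodedSmilesTensor:
    """Encode a corpus into a ``K x L x M`` tensor.

    ``max_length`` defaults to the longest string in the batch.  Encoding
    errors carry the offending item index.
    """
    if not smiles_list:
        raise ValueError("cannot encode an empty batch")
    L = max_length if max_length is not None else max(len(s) for s in smiles_list)
    data = np.zeros((len(smiles_list), L, dictionary.size), dtype=np.uint8)
    for k, s in enumerate(smiles_list):
        try:
            data[k] = encode_smiles(s, dictionary, L)
        except (ValueError, OutOfVocabularyError) as exc:
            raise type(exc)(f"item {k}: {exc}") from None
    return EncodedSmilesTensor(data=data, dictionary=dictionary)


def decode_smiles(matrix: np.ndarray, dictionary: SmilesDictionary) -> str:
    """Invert :func:`encode_smiles`; validates one-hot-then-padding layout."""
    if matrix.ndim != 2 or matrix.shape[1] != dictionary.size:
        raise ValueError("matrix shape does not match the dictionary")
    index_to_char = dictionary.index_to_char
    row_sums = matrix.sum(axis=1)
    chars: list[str] = []
    in_padding = False
    for row in range(matrix.shape[0]):
        if row_sums[row] == 0:
            in_padding = True
            continue
        if in_padding:
            raise ValueError(f"occupied row {row} follows a padding row")
        if row_sums[row] != 1:
            raise ValueError(f"row {row} has {int(row_sums[row])} set bits, expected 1")
        col = int(np.argmax(matrix[row]))
        chars.append(index_to_char[col + 1])
    return "".join(chars)
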