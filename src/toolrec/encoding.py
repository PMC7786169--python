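"""Tool dictionary and fixed-length vectorization of samples.

Tools are indexed 1..V in lexicographic order; index 0 is reserved for
padding and never assigned to a tool. A subsequence becomes an integer
vector of fixed length (default 25) padded with trailing zeros; a label
set becomes a multi-hot bit vector of length V.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .sequence_extraction import MAX_SEQUENCE_TOOLS, TrainingSample

PADDING_INDEX = 0


@dataclass(frozen=True)
class ToolVocabulary:
    """Bijection between canonical tool ids and indices 1..V (0 = padding)."""

    index_of: dict[str, int]

    def __post_init__(self) -> None:
        indices = sorted(self.index_of.values())
        if indices != list(range(1, len(indices) + 1)):
            raise ValidationError("indices must be contiguous 1..V")

    @property
    def size(self) -> int:
        return len(self.index_of)

    @property
    def id_of(self) -> dict[int, str]:
        return {i: t for t, i in self.index_of.items()}

    def __contains__(self, tool: str) -> bool:
        return tool in self.index_of

    def index(self, tool: str) -> int:
        try:
            return self.index_of[tool]
        except KeyError:
            raise LookupError(f"unknown tool {tool!r}") from None

    @classmethod
    def from_tools(cls, tools: Iterable[str]) -> "ToolVocabulary":
        ordered = sorted(set(tools))
        if not ordered:
            raise ValidationError("cannot build a vocabulary from no tools")
        return cls(index_of={t: i + 1 for i, t in enumerate(ordered)})


def build_vocabulary(samples: Sequence[TrainingSample]) -> ToolVocabulary:
    """Index every tool appearing in any subsequence or label set."""
    if not samples:
        raise ValidationError("empty corpus")
    tools: set[str] = set()
    for s in samples:
        tools.update(s.subsequence)
        tools.update(s.labels)
    return ToolVocabulary.from_tools(tools)


def encode_sequence(
    seq: Sequence[str], vocab: ToolVocabulary, max_len: int = MAX_SEQUENCE_TOOLS
) -> np.ndarray:
    """Integer vector of length ``max_len`` with trailing-zero padding."""
    if len(seq) > max_len:
        raise ValidationError(f"sequence of {len(seq)} tools exceeds max_len={max_len}")
    vec = np.zeros(max_len, dtype=np.int32)
    for pos, tool in enumerate(seq):
        vec[pos] = vocab.index(tool)
    return vec


def decode_sequence(vec: np.ndarray, vocab: ToolVocabulary) -> list[str]:
    """Inverse of :func:`encode_sequence`; stops at the first padding zero."""
    id_of = vocab.id_of
    out: list[str] = []
    for idx in vec:
        if idx == PADDING_INDEX:
            break
        out.append(id_of[int(idx)])
    return out


def encode_labels(labels: Iterable[str], vocab: ToolVocabulary) -> np.ndarray:
    """Multi-hot bit vector over the vocabulary (position = index - 1)."""
    vec = np.zeros(vocab.size, dtype=np.uint8)
    for tool in labels:
        vec[vocab.index(tool) - 1] = 1
    return vec


@dataclass(frozen=True)
class EncodedDataset:
    """Vectorized corpus: N x max_len index matrix and N x V label bits."""

    sequences: np.ndarray
    shared_labels: np.ndarray
    nonshared_labels: np.ndarray

    def __post_init__(self) -> None:
        n = self.sequences.shape[0]
        if self.shared_labels.shape[0] != n or self.nonshared_labels.shape[0] != n:
            raise ValidationError("matrix row counts disagree")
        if self.shared_labels.shape != self.nonshared_labels.shape:
            raise ValidationError("label matrices must share a shape")

    @property
    def n_samples(self) -> int:
        return self.sequences.shape[0]

    @property
    def vocabulary_size(self) -> int:
        return self.shared_labels.shape[1]

    @property
    def combined_labels(self) -> np.ndarray:
        return np.logical_or(self.shared_labels, self.nonshared_labels).astype(np.uint8)


def encode_dataset(
    samples: Sequence[TrainingSample],
    vocab: ToolVocabulary,
    max_len: int = MAX_SEQUENCE_TOOLS,
) -> EncodedDataset:
    """Vectorize a list of samples against a fixed vocabulary."""
    n = len(samples)
    sequences = np.zeros((n, max_len), dtype=np.int32)
    shared = np.zeros((n, vocab.size), dtype=np.uint8)
    nonshared = np.zeros((n, vocab.size), dtype=np.uint8)
    for row, s in enumerate(samples):
        sequences[row] = encode_sequence(s.subsequence, vocab, max_len)
        shared[row] = encode_labels(s.shared_labels, vocab)
        nonshared[row] = encode_labels(s.nonshared_labels, vocab)
    return EncodedDataset(
        sequences=sequences, shared_labels=shared, nonshared_labels=nonshared
    )
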