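"""Class-balanced batch sampling over training samples.

Raw fragment frequencies are heavily skewed: a few popular tools terminate
most fragments. Batches are therefore drawn by a two-stage uniform scheme
— first a label tool uniformly from the set of all label tools, then a
training sequence uniformly from the sequences carrying that label — which
flattens the label distribution seen by the optimizer. Sampling is with
replacement, so rare labels are oversampled within an epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .encoding import ToolVocabulary
from .errors import ValidationError
from .sequence_extraction import TrainingSample


@dataclass(frozen=True)
class LastToolIndex:
    """label tool index -> positions of training samples carrying it."""

    sample_ids_of: dict[int, list[int]]

    def __post_init__(self) -> None:
        for idx, ids in self.sample_ids_of.items():
            if not ids:
                raise ValidationError(f"empty sample list for tool index {idx}")

    @property
    def n_labels(self) -> int:
        return len(self.sample_ids_of)


def build_last_tool_index(
    train: Sequence[TrainingSample], vocab: ToolVocabulary
) -> LastToolIndex:
    """Index every training sample under each of its label tools."""
    if not train:
        raise ValidationError("empty training set")
    sample_ids_of: dict[int, list[int]] = {}
    for pos, sample in enumerate(train):
        for label in sample.labels:
            sample_ids_of.setdefault(vocab.index(label), []).append(pos)
    return LastToolIndex(sample_ids_of=sample_ids_of)


def sample_epoch_batches(
    index: LastToolIndex,
    n_samples: int,
    batch_size: int,
    rng_seed: int,
) -> Iterator[np.ndarray]:
    """Yield floor(n_samples / batch_size) balanced batches of sample ids.

    Each batch element: pick a label tool uniformly, then a sample
    uniformly from that tool's list. Deterministic for a fixed seed.
    """
    if batch_size < 1:
        raise ValidationError("batch_size must be >= 1")
    if n_samples < batch_size:
        raise ValidationError("n_samples must be >= batch_size")
    if not index.sample_ids_of:
        raise ValidationError("empty last-tool index")

    rng = np.random.default_rng(rng_seed)
    keys = sorted(index.sample_ids_of)
    pools = [np.asarray(index.sample_ids_of[k], dtype=np.int64) for k in keys]
    sizes = np.array([len(p) for p in pools])
    n_batches = n_samples // batch_size
    for _ in range(n_batches):
        labels = rng.integers(0, len(keys), size=batch_size)
        offsets = rng.integers(0, sizes[labels])
        yield np.array(
            [pools[lab][off] for lab, off in zip(labels, offsets)], dtype=np.int64
        )
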