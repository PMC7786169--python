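"""Decompose workflow DAGs into labelled tool sequences.

A workflow DAG is broken into every contiguous directed subpath of length
>= 2 tools. For a fragment of n tools the first n-1 form the training
subsequence and the n-th is a label, so a single subsequence can acquire
several labels across the corpus (the classification is multi-label). A
label is *shared* if at least one contributing workflow is shared; shared
membership takes precedence when the same label occurs in both categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_io import WorkflowGraph
from .errors import ContractError, ValidationError

MAX_SEQUENCE_TOOLS = 25  # fragments longer than this are discarded


@dataclass(frozen=True)
class TrainingSample:
    """An ordered tool subsequence with its shared / non-shared label sets."""

    subsequence: tuple[str, ...]
    shared_labels: frozenset[str]
    nonshared_labels: frozenset[str]

    def __post_init__(self) -> None:
        if not (self.shared_labels or self.nonshared_labels):
            raise ValidationError("a sample needs at least one label")
        if self.shared_labels & self.nonshared_labels:
            raise ValidationError("label sets must be disjoint (shared wins)")
        if "" in self.shared_labels or "" in self.nonshared_labels:
            raise ValidationError("empty label id")

    @property
    def labels(self) -> frozenset[str]:
        return self.shared_labels | self.nonshared_labels


@dataclass(frozen=True)
class SampleSplit:
    train: list[TrainingSample]
    test: list[TrainingSample]
    seed: int


def _successors(graph: WorkflowGraph) -> dict[str, list[str]]:
    succ: dict[str, list[str]] = {}
    for parent, child in graph.edges:
        succ.setdefault(parent, [])
        succ.setdefault(child, [])
        if child not in succ[parent]:
            succ[parent].append(child)
    return succ


def _assert_acyclic(succ: dict[str, list[str]]) -> None:
    # Kahn's algorithm; independent of networkx so the contract check
    # cannot share a bug with the reader's acyclicity filter.
    indeg = {n: 0 for n in succ}
    for children in succ.values():
        for c in children:
            indeg[c] += 1
    queue = [n for n, d in indeg.items() if d == 0]
    seen = 0
    while queue:
        node = queue.pop()
        seen += 1
        for c in succ[node]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if seen != len(succ):
        raise ContractError("graph contains a cycle")


def enumerate_paths(
    graph: WorkflowGraph, max_len: int | None = None
) -> list[tuple[str, ...]]:
    """Every contiguous directed subpath of >= 2 tools, deduplicated.

    Equivalent to listing every length->=2 contiguous fragment of every
    maximal source-to-sink path. Paths whose tool lists coincide (reached
    through different rows) are collapsed. Output is sorted by (length,
    tool ids) for determinism.
    """
    succ = _successors(graph)
    _assert_acyclic(succ)
    paths: set[tuple[str, ...]] = set()

    def extend(path: list[str]) -> None:
        if max_len is not None and len(path) >= max_len:
            return
        for child in succ[path[-1]]:
            path.append(child)
            paths.add(tuple(path))
            extend(path)
            path.pop()

    for start in succ:
        extend([start])
    return sorted(paths, key=lambda p: (len(p), p))


def extract_samples(
    graphs: list[WorkflowGraph], max_len: int = MAX_SEQUENCE_TOOLS
) -> list[TrainingSample]:
    """Pool fragment labels corpus-wide into multi-label training samples.

    Each enumerated fragment of n <= ``max_len`` tools contributes its
    first n-1 tools as a subsequence and its last tool as a label; longer
    fragments are discarded. Labels are pooled per unique subsequence; a
    label lands in ``shared_labels`` if any contributing workflow is
    shared, otherwise in ``nonshared_labels``.
    """
    if max_len < 2:
        raise ValidationError("max_len must be >= 2")
    pooled: dict[tuple[str, ...], dict[str, bool]] = {}
    for graph in graphs:
        for path in enumerate_paths(graph, max_len=max_len):
            sub, label = path[:-1], path[-1]
            labels = pooled.setdefault(sub, {})
            labels[label] = labels.get(label, False) or graph.is_shared
    return [
        TrainingSample(
            subsequence=sub,
            shared_labels=frozenset(l for l, s in labels.items() if s),
            nonshared_labels=frozenset(l for l, s in labels.items() if not s),
        )
        for sub, labels in sorted(pooled.items())
    ]


def split_train_test(
    samples: list[TrainingSample], fraction: float = 0.8, seed: int = 0
) -> SampleSplit:
    """Seeded uniform split over unique samples.

    Splitting by unique subsequence means a subsequence never appears in
    both partitions, so the test set cannot leak training contexts.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie in (0, 1)")
    if len(samples) < 2:
        raise ValidationError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    n_train = int(round(fraction * len(samples)))
    n_train = min(max(n_train, 1), len(samples) - 1)
    train = [samples[i] for i in sorted(perm[:n_train])]
    test = [samples[i] for i in sorted(perm[n_train:])]
    return SampleSplit(train=train, test=test, seed=seed)


def write_samples(samples: list[TrainingSample], path) -> None:
    """Export samples as TSV (comma-joined ids per cell)."""
    rows = [
        {
            "subsequence": ",".join(s.subsequence),
            "shared_labels": ",".join(sorted(s.shared_labels)),
            "nonshared_labels": ",".join(sorted(s.nonshared_labels)),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=["subsequence", "shared_labels", "nonshared_labels"]).to_csv(
        path, sep="\t", index=False
    )
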