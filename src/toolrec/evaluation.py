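"""Precision@k evaluation, usage metric, and multi-run experiments.

Precision@k counts how many of the k highest-scoring tools are true
labels (k = 2 with one hit gives 1/2 = 0.5). Precisions are averaged per
category — shared and non-shared separately, a sample being excluded from
a category it has no labels in — and experiments repeat the full
split/train/evaluate cycle with distinct seeds, reporting per-epoch mean
and standard deviation across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import EncodedDataset, build_vocabulary, encode_dataset
from .errors import ValidationError
from .sampling import build_last_tool_index
from .sequence_extraction import TrainingSample, split_train_test
from .usage_weights import ToolWeights

CATEGORIES = ("shared", "nonshared")


def _top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k best scores; ties broken by ascending tool index."""
    order = np.lexsort((np.arange(scores.shape[-1]), -scores))
    return order[:k]


def precision_at_k(scores: np.ndarray, true_labels, k: int):
    """Fraction of the top-k predicted tools that are true labels.

    Returns None (a skip-sample signal) when ``true_labels`` is empty:
    precision is undefined for a sample with no labels in the queried
    category, and such samples are excluded from means rather than
    scored zero.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > scores.shape[-1]:
        raise ValidationError(f"k={k} exceeds the vocabulary size {scores.shape[-1]}")
    true_set = set(int(i) for i in true_labels)
    if not true_set:
        return None
    hits = sum(1 for i in _top_k(scores, k) if int(i) in true_set)
    return hits / k


def _mean_precision(probs: np.ndarray, label_matrix: np.ndarray, k: int):
    """Mean precision@k over rows; rows without labels are excluded."""
    values = []
    for row_scores, row_labels in zip(probs, label_matrix):
        p = precision_at_k(row_scores, np.flatnonzero(row_labels), k)
        if p is not None:
            values.append(p)
    return float(np.mean(values)) if values else None


@dataclass
class PrecisionReport:
    """Mean precision per (k, category), optionally with run statistics.

    ``point`` holds single-evaluation means; a missing key means no test
    sample had labels in that category. ``trajectory_mean``/``sd`` hold
    per-epoch statistics across experiment runs.
    """

    point: dict[tuple[int, str], float] = field(default_factory=dict)
    trajectory_mean: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)
    trajectory_sd: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)
    n_runs: int = 1
    runs: list[dict] = field(default_factory=list)

    def to_table(self) -> pd.DataFrame:
        """Long-format export: (run, epoch, metric, category, k, value)."""
        rows = []
        for run_id, run in enumerate(self.runs):
            for (k, category), trajectory in run.items():
                for epoch, value in enumerate(trajectory):
                    rows.append(
                        {
                            "run": run_id,
                            "epoch": epoch,
                            "metric": f"precision@{k}",
                            "category": category,
                            "k": k,
                            "value": value,
                        }
                    )
        if not rows:
            rows = [
                {
                    "run": 0,
                    "epoch": -1,
                    "metric": f"precision@{k}",
                    "category": category,
                    "k": k,
                    "value": value,
                }
                for (k, category), value in sorted(self.point.items())
            ]
        return pd.DataFrame(
            rows, columns=["run", "epoch", "metric", "category", "k", "value"]
        )


def evaluate(
    model, test: EncodedDataset, ks: Sequence[int] = (1, 2)
) -> PrecisionReport:
    """Mean precision@k on a test set, shared and non-shared separately."""
    if test.n_samples == 0:
        raise ValidationError("empty test set")
    if test.vocabulary_size != model.vocab_size:
        raise ValidationError("test set vocabulary disagrees with the model")
    probs = model.predict(test.sequences)
    point: dict[tuple[int, str], float] = {}
    for category, matrix in (
        ("shared", test.shared_labels),
        ("nonshared", test.nonshared_labels),
    ):
        for k in ks:
            mean = _mean_precision(probs, matrix, k)
            if mean is not None:
                point[(k, category)] = mean
    return PrecisionReport(point=point)


def usage_frequency_of_predictions(
    model, test: EncodedDataset, weights: ToolWeights, k: int
) -> float:
    """Mean summed usage weight of the top-k predicted tools per sample."""
    probs = model.predict(test.sequences)
    w = weights.vector(model.vocab_size)
    totals = [w[_top_k(row, k)].sum() for row in probs]
    return float(np.mean(totals))


def run_experiments(
    corpus: list[TrainingSample],
    config,
    n_runs: int = 10,
    seeds: Sequence[int] | None = None,
    weights: ToolWeights | None = None,
    ks: Sequence[int] = (1, 2),
    use_sampler: bool = True,
) -> PrecisionReport:
    """Repeat split -> train -> evaluate; aggregate mean +/- SD per epoch.

    Each run re-splits the corpus with its own seed, trains a fresh model
    and evaluates precision@k per category after every epoch. Identical
    seed lists give identical reports.
    """
    from .recommender_model import build_model, train  # late: avoid cycle

    if n_runs < 2:
        raise ValidationError("n_runs must be >= 2")
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValidationError("need one seed per run")

    vocab = build_vocabulary(corpus)
    runs: list[dict[tuple[int, str], list[float]]] = []
    for seed in seeds:
        split = split_train_test(corpus, seed=seed)
        train_set = encode_dataset(split.train, vocab, max_len=config.max_len)
        test_set = encode_dataset(split.test, vocab, max_len=config.max_len)
        sampler = build_last_tool_index(split.train, vocab) if use_sampler else None
        model = build_model(config, vocab, tool_weights=weights, seed=seed)
        trajectories: dict[tuple[int, str], list[float]] = {
            (k, c): [] for k in ks for c in CATEGORIES
        }
        probs_by_epoch = _train_with_epoch_eval(
            model, train_set, test_set, sampler, weights, config, seed
        )
        for probs in probs_by_epoch:
            for category, matrix in (
                ("shared", test_set.shared_labels),
                ("nonshared", test_set.nonshared_labels),
            ):
                for k in ks:
                    mean = _mean_precision(probs, matrix, k)
                    if mean is not None:
                        trajectories[(k, category)].append(mean)
        runs.append({key: traj for key, traj in trajectories.items() if traj})

    report = PrecisionReport(n_runs=n_runs, runs=runs)
    keys = set().union(*(set(r) for r in runs))
    for key in keys:
        stacks = [np.asarray(r[key]) for r in runs if key in r]
        if len(stacks) != n_runs:
            continue  # category absent in some runs: no aggregate band
        arr = np.vstack(stacks)
        report.trajectory_mean[key] = arr.mean(axis=0)
        report.trajectory_sd[key] = arr.std(axis=0)
        report.point[key] = float(arr.mean(axis=0)[-1])
    return report


def _train_with_epoch_eval(
    model, train_set, test_set, sampler, weights, config, seed
) -> list[np.ndarray]:
    """Train once, collecting test-set scores after each epoch."""
    from .recommender_model import train

    probs_by_epoch: list[np.ndarray] = []
    train(
        model,
        train_set,
        sampler=sampler,
        weights=weights,
        config=config,
        seed=seed,
        epoch_callback=lambda m, _: probs_by_epoch.append(
            m.predict(test_set.sequences)
        ),
    )
    return probs_by_epoch
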