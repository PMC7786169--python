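"""Precision@k, usage metric and multi-run experiment aggregation."""

import numpy as np
import pytest

import toolrec as tr
from toolrec.errors import ValidationError
from toolrec.evaluation import _top_k
from toolrec.recommender_model import ModelConfig


def brute_precision(scores, true_labels, k):
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return sum(1 for i in order[:k] if i in true_labels) / k


class TestPrecisionAtK:
    def test_one_of_two_correct_is_half(self):
        scores = np.array([0.9, 0.8, 0.1, 0.05])
        assert tr.precision_at_k(scores, {0, 3}, k=2) == 0.5

    def test_all_correct(self):
        assert tr.precision_at_k(np.array([0.9, 0.8, 0.1]), {0, 1}, 2) == 1.0

    def test_none_correct(self):
        assert tr.precision_at_k(np.array([0.9, 0.8, 0.1]), {2}, 2) == 0.0

    def test_empty_labels_signal_skip(self):
        assert tr.precision_at_k(np.array([0.5, 0.5]), set(), 1) is None

    def test_k_larger_than_vocabulary_rejected(self):
        with pytest.raises(ValidationError):
            tr.precision_at_k(np.array([0.5, 0.5]), {0}, 3)

    def test_ties_broken_by_ascending_index(self):
        scores = np.array([0.5, 0.5, 0.5])
        assert list(_top_k(scores, 2)) == [0, 1]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            v = int(rng.integers(3, 20))
            scores = rng.uniform(0, 1, v)
            labels = set(
                int(i) for i in rng.choice(v, size=int(rng.integers(1, v)), replace=False)
            )
            k = int(rng.integers(1, v + 1))
            assert tr.precision_at_k(scores, labels, k) == brute_precision(
                scores, labels, k
            )

    def test_hit_count_monotone_in_k(self, rng):
        for _ in range(50):
            scores = rng.uniform(0, 1, 12)
            labels = {int(i) for i in rng.choice(12, size=4, replace=False)}
            hits = [
                k * tr.precision_at_k(scores, labels, k) for k in range(1, 13)
            ]
            assert all(b >= a for a, b in zip(hits, hits[1:]))


class _OracleModel:
    """Scores true labels highest: top-1 precision must be 1.0."""

    def __init__(self, label_matrix):
        self._labels = label_matrix.astype(float)
        self.vocab_size = label_matrix.shape[1]

    def predict(self, sequences):
        return 0.1 + 0.8 * self._labels[: len(sequences)]


class TestEvaluate:
    def test_oracle_model_scores_one(self, small_samples, small_vocab):
        ds = tr.encode_dataset(small_samples, small_vocab)
        model = _OracleModel(ds.combined_labels)
        report = tr.evaluate(model, ds)
        for (k, category), value in report.point.items():
            if k == 1:
                assert value == 1.0

    def test_mean_is_average_of_per_sample_precisions(self, small_vocab):
        v = small_vocab.size
        labels = np.zeros((2, v), dtype=np.uint8)
        labels[0, 0] = 1  # predicted top-1 -> precision 1.0
        labels[1, 1] = 1  # not predicted -> precision 0.0
        scores = np.zeros((2, v))
        scores[:, 0] = 0.9

        class Fixed:
            vocab_size = v

            def predict(self, sequences):
                return scores

        ds = tr.EncodedDataset(
            sequences=np.zeros((2, 25), dtype=np.int32),
            shared_labels=labels,
            nonshared_labels=np.zeros_like(labels),
        )
        report = tr.evaluate(Fixed(), ds, ks=(1,))
        assert report.point[(1, "shared")] == 0.5
        # nonshared has no labelled samples: absent, not zero
        assert (1, "nonshared") not in report.point

    def test_vocabulary_mismatch_rejected(self, trained_model, small_vocab):
        bad = tr.EncodedDataset(
            sequences=np.zeros((1, 25), dtype=np.int32),
            shared_labels=np.ones((1, small_vocab.size + 1), dtype=np.uint8),
            nonshared_labels=np.zeros((1, small_vocab.size + 1), dtype=np.uint8),
        )
        with pytest.raises(ValidationError):
            tr.evaluate(trained_model["model"], bad)


class TestUsageFrequencyOfPredictions:
    def test_all_unit_weights_give_k(self, trained_model):
        metric = tr.usage_frequency_of_predictions(
            trained_model["model"],
            trained_model["test_set"],
            tr.ToolWeights(),
            k=2,
        )
        assert metric == pytest.approx(2.0)

    def test_matches_per_sample_loop(self, trained_model, rng):
        model = trained_model["model"]
        test = trained_model["test_set"]
        weights = tr.ToolWeights(
            weight_of={
                i + 1: float(w)
                for i, w in enumerate(rng.uniform(0.5, 4.0, model.vocab_size))
            }
        )
        k = 3
        metric = tr.usage_frequency_of_predictions(model, test, weights, k)
        w = weights.vector(model.vocab_size)
        probs = model.predict(test.sequences[:20])
        manual = [w[_top_k(row, k)].sum() for row in probs]
        full_probs = model.predict(test.sequences)
        full = np.mean([w[_top_k(row, k)].sum() for row in full_probs])
        assert metric == pytest.approx(full)
        assert manual == pytest.approx(
            [w[_top_k(row, k)].sum() for row in full_probs[:20]]
        )


@pytest.fixture(scope="module")
def tiny_report():
    spec = tr.GrammarSpec(n_tools=15, n_layers=3, fanout=2, n_workflows=60, seed=5)
    graphs, _ = tr.generate_corpus(spec)
    corpus = tr.extract_samples(graphs)
    config = ModelConfig(
        embedding_dim=8, gru_units=12, epochs=3, batch_size=8, learning_rate=0.02
    )
    return tr.run_experiments(corpus, config, n_runs=2, seeds=[0, 1])


class TestRunExperiments:
    def test_aggregates_cover_runs_and_epochs(self, tiny_report):
        assert tiny_report.n_runs == 2
        for key, mean in tiny_report.trajectory_mean.items():
            assert mean.shape == (3,)
            assert tiny_report.trajectory_sd[key].shape == (3,)
            assert (tiny_report.trajectory_sd[key] >= 0).all()

    def test_identical_seeds_give_zero_sd(self):
        spec = tr.GrammarSpec(n_tools=15, n_layers=3, fanout=2, n_workflows=60, seed=5)
        graphs, _ = tr.generate_corpus(spec)
        corpus = tr.extract_samples(graphs)
        config = ModelConfig(
            embedding_dim=8, gru_units=12, epochs=2, batch_size=8, learning_rate=0.02
        )
        report = tr.run_experiments(corpus, config, n_runs=2, seeds=[3, 3])
        for sd in report.trajectory_sd.values():
            assert np.allclose(sd, 0.0)

    def test_table_export_shape(self, tiny_report):
        table = tiny_report.to_table()
        assert list(table.columns) == ["run", "epoch", "metric", "category", "k", "value"]
        assert (table["value"] <= 1).all() and (table["value"] >= 0).all()
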