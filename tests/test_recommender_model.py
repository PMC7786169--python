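"""Network architecture, loss, training loop, tuning and the model store."""

import numpy as np
import pytest
from scipy.special import expit

import toolrec as tr
from toolrec.errors import CorruptStoreError, ValidationError
from toolrec.recommender_model import ModelConfig, tune_hyperparameters


def scalar_loss_reference(p_true, p_pred, w, eps=1e-7):
    """Plain Python loop implementing the weighted cross-entropy."""
    total = 0.0
    t = len(p_true)
    for a, b, wi in zip(p_true, p_pred, w):
        b = min(max(b, eps), 1 - eps)
        total += (a * np.log(b) + (1 - a) * np.log(1 - b)) * wi
    return -total / t


class TestSigmoid:
    def test_symmetry_point(self):
        assert tr.sigmoid(0.0) == 0.5

    def test_value_at_ten(self):
        assert tr.sigmoid(10.0) == pytest.approx(0.9999546, abs=1e-7)

    def test_identity_and_agreement_with_expit(self, rng):
        x = rng.normal(0, 50, size=200)
        s = tr.sigmoid(x)
        assert np.allclose(s + tr.sigmoid(-x), 1.0)
        assert np.allclose(s, expit(x))
        assert np.isfinite(tr.sigmoid(np.array([-1e4, 1e4]))).all()


class TestWeightedCrossentropy:
    def test_perfect_prediction_is_near_zero(self):
        eps = 1e-7
        loss = tr.weighted_crossentropy([1, 0], [1 - eps, eps], [1, 1])
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_prediction_is_ln2(self):
        loss = tr.weighted_crossentropy([1, 0], [0.5, 0.5], [1, 1])
        assert loss == pytest.approx(np.log(2), abs=1e-12)

    def test_linear_in_weights(self, rng):
        y = rng.integers(0, 2, 16).astype(float)
        p = rng.uniform(0.05, 0.95, 16)
        w = rng.uniform(0.5, 2.0, 16)
        assert tr.weighted_crossentropy(y, p, 2 * w) == pytest.approx(
            2 * tr.weighted_crossentropy(y, p, w)
        )

    def test_matches_scalar_loop_on_random_triples(self, rng):
        for _ in range(100):
            t = int(rng.integers(2, 30))
            y = rng.integers(0, 2, t).astype(float)
            p = rng.uniform(0.0, 1.0, t)
            w = rng.uniform(0.1, 5.0, t)
            assert tr.weighted_crossentropy(y, p, w) == pytest.approx(
                scalar_loss_reference(y, p, w), abs=1e-10
            )

    def test_misclassification_cost_scales_with_weight(self):
        # a confidently wrong label with w=10 costs 10x the same error at w=1
        y, p = np.array([1.0]), np.array([0.01])
        assert tr.weighted_crossentropy(y, p, [10.0]) == pytest.approx(
            10 * tr.weighted_crossentropy(y, p, [1.0])
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            tr.weighted_crossentropy([1, 0], [0.5], [1, 1])


def tiny_config(**kw):
    base = dict(
        embedding_dim=4,
        gru_units=6,
        dropout_embed=0.0,
        dropout_between=0.0,
        dropout_out=0.0,
        learning_rate=0.01,
        batch_size=4,
        epochs=2,
        max_len=6,
    )
    base.update(kw)
    return ModelConfig(**base)


class TestBuildModel:
    def test_parameter_count_closed_form(self):
        v, d, h = 10, 8, 16
        model = tr.build_model(
            tiny_config(embedding_dim=d, gru_units=h), v
        )
        gru1 = 3 * (d * h + h * h + h)
        gru2 = 3 * (h * h + h * h + h)
        dense = h * v + v
        assert model.n_parameters == (v + 1) * d + gru1 + gru2 + dense

    def test_output_dimension_and_range(self, rng):
        model = tr.build_model(tiny_config(), 7)
        x = rng.integers(0, 8, size=(5, 6))
        probs = model.predict(x)
        assert probs.shape == (5, 7)
        assert ((probs > 0) & (probs < 1)).all()

    def test_padding_row_is_zero(self):
        model = tr.build_model(tiny_config(), 7)
        assert not model.params["emb"][0].any()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            ModelConfig(dropout_embed=1.0)
        with pytest.raises(ValidationError):
            ModelConfig(learning_rate=0.0)


class TestGradients:
    def test_finite_difference_check(self, rng):
        model = tr.build_model(tiny_config(), 5, seed=1)
        x = np.array([[1, 2, 3, 0, 0, 0], [4, 5, 1, 2, 0, 0]])
        y = rng.integers(0, 2, (2, 5)).astype(float)
        w = rng.uniform(0.5, 2.0, 5)
        _, grads = model._loss_and_grads(x, y, w)
        eps = 1e-6
        for name, param in model.params.items():
            for _ in range(4):
                idx = tuple(int(rng.integers(0, s)) for s in param.shape)
                if name == "emb" and idx[0] == 0:
                    continue  # frozen padding row
                orig = param[idx]
                param[idx] = orig + eps
                up, _ = model._loss_and_grads(x, y, w)
                param[idx] = orig - eps
                down, _ = model._loss_and_grads(x, y, w)
                param[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[name][idx] == pytest.approx(
                    numeric, rel=1e-4, abs=1e-7
                ), name

    def test_loss_gradient_wrt_predictions(self, rng):
        # d loss / d p_i = -(w_i / T) * (y_i / p_i - (1 - y_i) / (1 - p_i))
        y = rng.integers(0, 2, 6).astype(float)
        p = rng.uniform(0.2, 0.8, 6)
        w = rng.uniform(0.5, 2.0, 6)
        eps = 1e-7
        for i in range(6):
            up, down = p.copy(), p.copy()
            up[i] += eps
            down[i] -= eps
            numeric = (
                tr.weighted_crossentropy(y, up, w)
                - tr.weighted_crossentropy(y, down, w)
            ) / (2 * eps)
            analytic = -(w[i] / 6) * (y[i] / p[i] - (1 - y[i]) / (1 - p[i]))
            assert numeric == pytest.approx(analytic, rel=1e-4)


class TestTrain:
    def test_loss_decreases_on_synthetic_corpus(self, trained_model):
        history = trained_model["history"]
        assert history.train_loss[-1] < history.train_loss[0]

    def test_epoch_count_matches_history(self, trained_model):
        assert trained_model["history"].n_epochs == trained_model["model"].config.epochs

    def test_uniform_weights_equal_plain_bce_trajectory(
        self, small_samples, small_vocab
    ):
        split = tr.split_train_test(small_samples, seed=1)
        dataset = tr.encode_dataset(split.train, small_vocab)
        sampler = tr.build_last_tool_index(split.train, small_vocab)
        config = tiny_config(embedding_dim=8, gru_units=8, epochs=2, max_len=25)
        runs = []
        for weights in (None, tr.ToolWeights(weight_of={}, default_weight=1.0)):
            model = tr.build_model(config, small_vocab, seed=2)
            _, history = tr.train(
                model, dataset, sampler=sampler, weights=weights, seed=2
            )
            runs.append(history.train_loss)
        assert runs[0] == runs[1]

    def test_training_is_deterministic_per_seed(self, small_samples, small_vocab):
        split = tr.split_train_test(small_samples, seed=1)
        dataset = tr.encode_dataset(split.train, small_vocab)
        config = tiny_config(embedding_dim=8, gru_units=8, epochs=1, max_len=25)
        losses = []
        for _ in range(2):
            model = tr.build_model(config, small_vocab, seed=4)
            _, history = tr.train(model, dataset, seed=4)
            losses.append(history.train_loss)
        assert losses[0] == losses[1]


class TestTuneHyperparameters:
    SPACE = {
        "embedding_dim": (4, 8),
        "gru_units": (4, 8),
        "learning_rate": (1e-3, 1e-2, "log"),
        "batch_size": (4, 8),
    }

    @pytest.fixture(scope="class")
    def corpus(self):
        spec = tr.GrammarSpec(n_tools=12, n_layers=3, fanout=2, n_workflows=40, seed=11)
        graphs, _ = tr.generate_corpus(spec)
        return tr.extract_samples(graphs)

    def test_records_requested_evaluations(self, corpus):
        config, trials = tune_hyperparameters(
            corpus, self.SPACE, n_evals=6, seed=0, tune_epochs=1, return_trials=True
        )
        assert len(trials) == 6
        best = min(s for _, s in trials)
        assert best <= np.median([s for _, s in trials])

    def test_returned_config_inside_ranges(self, corpus):
        config = tune_hyperparameters(
            corpus, self.SPACE, n_evals=4, seed=1, tune_epochs=1
        )
        assert 4 <= config.embedding_dim <= 8
        assert 4 <= config.gru_units <= 8
        assert 1e-3 <= config.learning_rate <= 1e-2
        assert 4 <= config.batch_size <= 8

    def test_one_point_space_returns_that_point(self, corpus):
        space = {"embedding_dim": 4, "gru_units": 4, "learning_rate": 5e-3}
        config = tune_hyperparameters(
            corpus, space, n_evals=3, seed=2, tune_epochs=1
        )
        assert (config.embedding_dim, config.gru_units) == (4, 4)
        assert config.learning_rate == 5e-3

    def test_empty_space_rejected(self, corpus):
        with pytest.raises(ValidationError):
            tune_hyperparameters(corpus, {}, n_evals=2)


class TestModelStore:
    def test_round_trip_predictions_bitwise(self, trained_model, tmp_path, rng):
        model = trained_model["model"]
        path = tmp_path / "model.h5"
        tr.save_model(model, path)
        loaded = tr.load_model(path)
        x = trained_model["test_set"].sequences[:16]
        assert np.array_equal(model.predict(x), loaded.predict(x))
        assert loaded.vocabulary.index_of == model.vocabulary.index_of
        assert loaded.shared_tools == model.shared_tools

    def test_store_contains_three_groups(self, trained_model, tmp_path):
        import h5py

        path = tmp_path / "model.h5"
        tr.save_model(trained_model["model"], path)
        with h5py.File(path) as store:
            assert set(store) >= {"network", "vocabulary", "tool_weights"}
            assert store["vocabulary"]["tools"].shape[0] == (
                store["network"]["out_b"].shape[0]
            )

    def test_missing_dictionary_group_is_corrupt(self, trained_model, tmp_path):
        import h5py

        path = tmp_path / "model.h5"
        tr.save_model(trained_model["model"], path)
        with h5py.File(path, "a") as store:
            del store["vocabulary"]
        with pytest.raises(CorruptStoreError):
            tr.load_model(path)
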