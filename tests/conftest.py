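"""Shared fixtures: small synthetic corpora and a quickly trained model."""

import numpy as np
import pytest

import toolrec as tr
from toolrec.recommender_model import ModelConfig


@pytest.fixture(scope="session")
def fig1_graph():
    """The canonical worked example: A->B->C branching into D and E."""
    return tr.WorkflowGraph(
        workflow_id="wf1",
        edges=(("A", "B"), ("B", "C"), ("C", "D"), ("C", "E")),
        is_shared=True,
    )


@pytest.fixture(scope="session")
def small_corpus():
    spec = tr.GrammarSpec(
        n_tools=24, n_layers=4, fanout=2, n_workflows=250, seed=7
    )
    return tr.generate_corpus(spec)


@pytest.fixture(scope="session")
def small_samples(small_corpus):
    graphs, _ = small_corpus
    return tr.extract_samples(graphs)


@pytest.fixture(scope="session")
def small_vocab(small_samples):
    return tr.build_vocabulary(small_samples)


@pytest.fixture(scope="session")
def trained_model(small_samples, small_vocab):
    """A small model trained for a few epochs; shared across test modules."""
    split = tr.split_train_test(small_samples, seed=3)
    train_set = tr.encode_dataset(split.train, small_vocab)
    test_set = tr.encode_dataset(split.test, small_vocab)
    sampler = tr.build_last_tool_index(split.train, small_vocab)
    config = ModelConfig(
        embedding_dim=16,
        gru_units=32,
        epochs=6,
        batch_size=8,
        learning_rate=0.01,
    )
    shared_tools = frozenset(
        t for s in small_samples for t in s.shared_labels
    )
    model = tr.build_model(
        config, small_vocab, shared_tools=shared_tools, seed=3
    )
    model, history = tr.train(
        model, train_set, sampler=sampler, test_dataset=test_set, seed=3
    )
    return {
        "model": model,
        "history": history,
        "split": split,
        "train_set": train_set,
        "test_set": test_set,
        "vocab": small_vocab,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dag(rng, n_nodes, p_edge=0.35):
    """A random DAG over lettered tools, edges respecting a random order."""
    names = [f"n{i:02d}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges.append((names[order[i]], names[order[j]]))
    if not edges:
        edges = [(names[order[0]], names[order[1]])]
    return tr.WorkflowGraph(
        workflow_id="rand", edges=tuple(edges), is_shared=bool(rng.random() < 0.5)
    )
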