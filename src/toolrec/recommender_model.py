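"""The GRU multi-label classifier: architecture, loss, training, store.

The network models p(x_T | x_1..x_{T-1}): given an encoded tool
subsequence it scores every tool in the vocabulary as a candidate next
tool. Architecture (in order): embedding over V+1 indices with the
padding row masked, dropout, GRU (ELU candidate activation, sequences
returned), dropout, GRU (ELU), dropout, dense layer of V sigmoid units.
Training minimizes a usage-weighted binary cross-entropy

    loss = -(1/T) * sum_i [ p_i^a log p_i^b + (1 - p_i^a) log(1 - p_i^b) ] * w_i

(T = vocabulary size, w_i the tool's usage weight) with an RMSProp
optimizer over class-balanced batches.

The whole network — forward pass, backpropagation through time and the
optimizer — is implemented directly on NumPy arrays, which keeps the
model store portable and the training loop deterministic under a fixed
seed. Hyperparameters are tuned by sequential model-based (Bayesian)
optimization with a Gaussian-process surrogate and expected-improvement
acquisition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable

import h5py
import numpy as np
from scipy.special import ndtr

from .encoding import EncodedDataset, ToolVocabulary
from .errors import CorruptStoreError, ValidationError
from .sampling import LastToolIndex, sample_epoch_batches
from .sequence_extraction import TrainingSample, split_train_test
from .usage_weights import ToolWeights

logger = logging.getLogger(__name__)

EPSILON = 1e-7  # prediction clip before the log
RMSPROP_RHO = 0.9
RMSPROP_EPS = 1e-7


# --------------------------------------------------------------------------
# activations and loss
# --------------------------------------------------------------------------

def sigmoid(x):
    """Logistic function 1 / (1 + e^-x), stable for large |x|."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray, fx: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, fx + 1.0)


def weighted_crossentropy(p_true, p_pred, w, eps: float = EPSILON) -> float:
    """Usage-weighted binary cross-entropy over a label bit vector.

    Reduces to plain multi-label BCE when every w_i = 1 and is linear in
    the weights. Predictions are clipped into [eps, 1 - eps] before the
    logarithm.
    """
    p_true = np.asarray(p_true, dtype=np.float64)
    p_pred = np.asarray(p_pred, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if not (p_true.shape == p_pred.shape and w.shape[-1] == p_true.shape[-1]):
        raise ValidationError("p_true, p_pred and w must have matching lengths")
    p = np.clip(p_pred, eps, 1.0 - eps)
    per_label = (p_true * np.log(p) + (1.0 - p_true) * np.log1p(-p)) * w
    t = p_true.shape[-1]
    return float(-np.sum(per_label, axis=-1).mean() / t)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Tunable knobs of the network and its training loop."""

    embedding_dim: int = 64
    gru_units: int = 64
    dropout_embed: float = 0.1
    dropout_between: float = 0.1
    dropout_out: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 10
    max_len: int = 25

    def __post_init__(self) -> None:
        if self.embedding_dim < 1 or self.gru_units < 1:
            raise ValidationError("layer sizes must be positive")
        for name in ("dropout_embed", "dropout_between", "dropout_out"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValidationError(f"{name} must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1 or self.max_len < 2:
            raise ValidationError("batch_size, epochs, max_len out of range")


# search ranges used when the caller gives none; every entry overridable
DEFAULT_SEARCH_SPACE: dict[str, object] = {
    "embedding_dim": (32, 512),
    "gru_units": (32, 512),
    "dropout_embed": (0.0, 0.5),
    "dropout_between": (0.0, 0.5),
    "dropout_out": (0.0, 0.5),
    "learning_rate": (1e-4, 1e-2, "log"),
    "batch_size": (32, 256),
}


@dataclass
class TrainingHistory:
    """Per-epoch training loss, validation loss and precision@k."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    precision_at_1: list[float] = field(default_factory=list)
    precision_at_2: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


# --------------------------------------------------------------------------
# parameter initialization
# --------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def _init_params(
    config: ModelConfig, vocab_size: int, seed: int
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    d, h, v = config.embedding_dim, config.gru_units, vocab_size
    params: dict[str, np.ndarray] = {}
    emb = rng.uniform(-0.05, 0.05, size=(v + 1, d))
    emb[0] = 0.0  # padding row, never trained
    params["emb"] = emb
    for prefix, in_dim in (("g1", d), ("g2", h)):
        for gate in ("z", "r", "h"):
            params[f"{prefix}_W{gate}"] = _glorot(rng, in_dim, h)
            params[f"{prefix}_U{gate}"] = _orthogonal(rng, h)
            params[f"{prefix}_b{gate}"] = np.zeros(h)
    params["out_W"] = _glorot(rng, h, v)
    params["out_b"] = np.zeros(v)
    return params


# --------------------------------------------------------------------------
# GRU forward / backward (batch, time-major caches)
# --------------------------------------------------------------------------

def _gru_forward(params, prefix, x, mask):
    """Run one GRU layer over x (B,T,D) with mask (B,T); ELU candidate.

    Gate equations (h_prev carried across masked/padded steps):
        z = sigmoid(x Wz + h_prev Uz + bz)
        r = sigmoid(x Wr + h_prev Ur + br)
        hh = elu(x Wh + (r * h_prev) Uh + bh)
        h = z * h_prev + (1 - z) * hh
    Returns the full hidden sequence (B,T,H) and the backward cache.
    """
    Wz, Wr, Wh = params[f"{prefix}_Wz"], params[f"{prefix}_Wr"], params[f"{prefix}_Wh"]
    Uz, Ur, Uh = params[f"{prefix}_Uz"], params[f"{prefix}_Ur"], params[f"{prefix}_Uh"]
    bz, br, bh = params[f"{prefix}_bz"], params[f"{prefix}_br"], params[f"{prefix}_bh"]
    B, T, _ = x.shape
    H = Wz.shape[1]
    h = np.zeros((B, H))
    seq = np.zeros((B, T, H))
    cache = {"x": x, "mask": mask, "h_prev": [], "z": [], "r": [], "sh": [], "hh": []}
    for t in range(T):
        xt = x[:, t, :]
        m = mask[:, t][:, None]
        z = sigmoid(xt @ Wz + h @ Uz + bz)
        r = sigmoid(xt @ Wr + h @ Ur + br)
        sh = xt @ Wh + (r * h) @ Uh + bh
        hh = _elu(sh)
        h_new = z * h + (1.0 - z) * hh
        cache["h_prev"].append(h)
        cache["z"].append(z)
        cache["r"].append(r)
        cache["sh"].append(sh)
        cache["hh"].append(hh)
        h = m * h_new + (1.0 - m) * h
        seq[:, t, :] = h
    return seq, cache


def _gru_backward(params, prefix, cache, d_seq=None, d_last=None):
    """Backprop through time for one GRU layer.

    ``d_seq`` carries per-timestep gradients (layer returned sequences);
    ``d_last`` a gradient on the final hidden state only.
    Returns (dx, grads) with dx shaped like the layer input.
    """
    Wz, Wr, Wh = params[f"{prefix}_Wz"], params[f"{prefix}_Wr"], params[f"{prefix}_Wh"]
    Uz, Ur, Uh = params[f"{prefix}_Uz"], params[f"{prefix}_Ur"], params[f"{prefix}_Uh"]
    x, mask = cache["x"], cache["mask"]
    B, T, D = x.shape
    H = Wz.shape[1]
    grads = {
        f"{prefix}_{n}": np.zeros_like(params[f"{prefix}_{n}"])
        for n in ("Wz", "Wr", "Wh", "Uz", "Ur", "Uh", "bz", "br", "bh")
    }
    dx = np.zeros_like(x)
    dh = np.zeros((B, H)) if d_last is None else d_last.copy()
    for t in range(T - 1, -1, -1):
        if d_seq is not None:
            dh = dh + d_seq[:, t, :]
        m = mask[:, t][:, None]
        h_prev = cache["h_prev"][t]
        z, r = cache["z"][t], cache["r"][t]
        sh, hh = cache["sh"][t], cache["hh"][t]
        g = m * dh  # gradient that flows through the cell update
        dz_pre = g * (h_prev - hh) * z * (1.0 - z)
        dhh_pre = g * (1.0 - z) * _elu_grad(sh, hh)
        dq = dhh_pre @ Uh.T  # gradient on (r * h_prev)
        dr_pre = dq * h_prev * r * (1.0 - r)
        xt = x[:, t, :]
        grads[f"{prefix}_Wz"] += xt.T @ dz_pre
        grads[f"{prefix}_Wr"] += xt.T @ dr_pre
        grads[f"{prefix}_Wh"] += xt.T @ dhh_pre
        grads[f"{prefix}_Uz"] += h_prev.T @ dz_pre
        grads[f"{prefix}_Ur"] += h_prev.T @ dr_pre
        grads[f"{prefix}_Uh"] += (r * h_prev).T @ dhh_pre
        grads[f"{prefix}_bz"] += dz_pre.sum(axis=0)
        grads[f"{prefix}_br"] += dr_pre.sum(axis=0)
        grads[f"{prefix}_bh"] += dhh_pre.sum(axis=0)
        dx[:, t, :] = dz_pre @ Wz.T + dr_pre @ Wr.T + dhh_pre @ Wh.T
        dh = (
            (1.0 - m) * dh
            + g * z
            + dz_pre @ Uz.T
            + dr_pre @ Ur.T
            + dq * r
        )
    return dx, grads


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class RecommenderModel:
    """Trained (or trainable) network plus vocabulary, weights, categories.

    ``shared_tools`` persists which tools ever occurred as shared labels
    during extraction; inference uses it to split the score vector into
    the shared and non-shared recommendation sets.
    """

    def __init__(
        self,
        config: ModelConfig,
        vocab_size: int,
        vocabulary: ToolVocabulary | None = None,
        tool_weights: ToolWeights | None = None,
        shared_tools: frozenset[str] | None = None,
        seed: int = 0,
        params: dict[str, np.ndarray] | None = None,
    ) -> None:
        if vocab_size < 2:
            raise ValidationError("vocabulary must contain at least 2 tools")
        if vocabulary is not None and vocabulary.size != vocab_size:
            raise ValidationError("vocabulary size disagrees with vocab_size")
        self.config = config
        self.vocabulary = vocabulary
        self.tool_weights = tool_weights
        self.shared_tools = shared_tools
        self.params = params if params is not None else _init_params(
            config, vocab_size, seed
        )

    @property
    def vocab_size(self) -> int:
        return self.params["out_b"].shape[0]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # ---- forward -----------------------------------------------------

    def _forward(self, x: np.ndarray, dropout_rng: np.random.Generator | None):
        """Full forward pass; dropout only when a generator is supplied."""
        cfg = self.config
        mask = (x > 0).astype(np.float64)
        e = self.params["emb"][x]
        cache: dict[str, object] = {"x": x, "mask": mask}

        def drop(a: np.ndarray, rate: float, key: str) -> np.ndarray:
            if dropout_rng is None or rate <= 0.0:
                cache[key] = None
                return a
            keep = 1.0 - rate
            m = (dropout_rng.random(a.shape) < keep) / keep
            cache[key] = m
            return a * m

        e_d = drop(e, cfg.dropout_embed, "m_embed")
        h1, c1 = _gru_forward(self.params, "g1", e_d, mask)
        h1_d = drop(h1, cfg.dropout_between, "m_between")
        h2_seq, c2 = _gru_forward(self.params, "g2", h1_d, mask)
        h2 = h2_seq[:, -1, :]  # padding-masked: equals state at last real tool
        h2_d = drop(h2, cfg.dropout_out, "m_out")
        logits = h2_d @ self.params["out_W"] + self.params["out_b"]
        probs = sigmoid(logits)
        cache.update({"c1": c1, "c2": c2, "e_d": e_d, "h1_d": h1_d, "h2_d": h2_d})
        return probs, cache

    def predict(self, sequences: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Deterministic scores (N, V), each strictly within (0, 1)."""
        x = np.atleast_2d(np.asarray(sequences, dtype=np.int64))
        chunks = [
            self._forward(x[i : i + batch_size], dropout_rng=None)[0]
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    # ---- backward ----------------------------------------------------

    def _loss_and_grads(
        self,
        x: np.ndarray,
        y: np.ndarray,
        w_vec: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
    ):
        """One training step's loss and parameter gradients."""
        probs, cache = self._forward(x, dropout_rng)
        loss = weighted_crossentropy(y, probs, w_vec)
        b, v = probs.shape
        dlogits = (probs - y) * w_vec / (v * b)

        grads: dict[str, np.ndarray] = {}
        grads["out_W"] = cache["h2_d"].T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        dh2 = dlogits @ self.params["out_W"].T
        if cache["m_out"] is not None:
            dh2 = dh2 * cache["m_out"]
        dh1_d, g2 = _gru_backward(self.params, "g2", cache["c2"], d_last=dh2)
        grads.update(g2)
        if cache["m_between"] is not None:
            dh1_d = dh1_d * cache["m_between"]
        de_d, g1 = _gru_backward(self.params, "g1", cache["c1"], d_seq=dh1_d)
        grads.update(g1)
        if cache["m_embed"] is not None:
            de_d = de_d * cache["m_embed"]
        demb = np.zeros_like(self.params["emb"])
        np.add.at(demb, cache["x"].reshape(-1), de_d.reshape(-1, de_d.shape[-1]))
        demb[0] = 0.0  # padding embedding is frozen
        grads["emb"] = demb
        return loss, grads


def build_model(
    config: ModelConfig,
    vocab: ToolVocabulary | int,
    tool_weights: ToolWeights | None = None,
    shared_tools: Iterable[str] | None = None,
    seed: int = 0,
) -> RecommenderModel:
    """Construct an untrained model for a vocabulary (or its size)."""
    if isinstance(vocab, ToolVocabulary):
        vocabulary, size = vocab, vocab.size
    else:
        vocabulary, size = None, int(vocab)
    return RecommenderModel(
        config=config,
        vocab_size=size,
        vocabulary=vocabulary,
        tool_weights=tool_weights,
        shared_tools=frozenset(shared_tools) if shared_tools is not None else None,
        seed=seed,
    )


# --------------------------------------------------------------------------
# optimizer and training loop
# --------------------------------------------------------------------------

class _RMSProp:
    def __init__(self, learning_rate: float):
        self.lr = learning_rate
        self.cache: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        for name, g in grads.items():
            c = self.cache.get(name)
            if c is None:
                c = np.zeros_like(g)
            c = RMSPROP_RHO * c + (1.0 - RMSPROP_RHO) * g * g
            self.cache[name] = c
            params[name] -= self.lr * g / (np.sqrt(c) + RMSPROP_EPS)


def _derive_seed(seed: int, *salt: int) -> int:
    ss = np.random.SeedSequence([int(seed) % (2**31), *[int(s) for s in salt]])
    return int(ss.generate_state(1)[0] % (2**31))


def train(
    model: RecommenderModel,
    dataset: EncodedDataset,
    sampler: LastToolIndex | None = None,
    weights: ToolWeights | None = None,
    config: ModelConfig | None = None,
    test_dataset: EncodedDataset | None = None,
    seed: int = 0,
    epoch_callback=None,
) -> tuple[RecommenderModel, TrainingHistory]:
    """Train in place over class-balanced epochs; returns (model, history).

    The loss is computed against the combined (shared OR non-shared)
    label matrix — the shared/non-shared distinction only matters at
    ranking and evaluation time. When ``sampler`` is None, plain shuffled
    mini-batches are used instead of balanced two-stage sampling.
    """
    cfg = config or model.config
    v = model.vocab_size
    if dataset.vocabulary_size != v:
        raise ValidationError("dataset vocabulary size disagrees with the model")
    w_vec = (weights or model.tool_weights or ToolWeights()).vector(v)
    y_all = dataset.combined_labels.astype(np.float64)
    x_all = dataset.sequences.astype(np.int64)
    n = x_all.shape[0]
    batch_size = min(cfg.batch_size, n)
    opt = _RMSProp(cfg.learning_rate)
    dropout_rng = np.random.default_rng(_derive_seed(seed, 1))
    shuffle_rng = np.random.default_rng(_derive_seed(seed, 2))
    history = TrainingHistory()
    for epoch in range(cfg.epochs):
        if sampler is not None:
            batches = sample_epoch_batches(
                sampler, n, batch_size, rng_seed=_derive_seed(seed, 3, epoch)
            )
        else:
            perm = shuffle_rng.permutation(n)
            batches = (
                perm[i * batch_size : (i + 1) * batch_size]
                for i in range(n // batch_size)
            )
        losses = []
        for ids in batches:
            loss, grads = model._loss_and_grads(
                x_all[ids], y_all[ids], w_vec, dropout_rng
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss!r}; "
                    "lower the learning rate"
                )
            opt.step(model.params, grads)
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)) if losses else float("nan"))
        if test_dataset is not None:
            from .evaluation import _mean_precision  # local: avoids import cycle

            probs = model.predict(test_dataset.sequences)
            y_test = test_dataset.combined_labels.astype(np.float64)
            history.val_loss.append(weighted_crossentropy(y_test, probs, w_vec))
            history.precision_at_1.append(_mean_precision(probs, y_test, 1))
            history.precision_at_2.append(_mean_precision(probs, y_test, 2))
        if epoch_callback is not None:
            epoch_callback(model, epoch)
        logger.debug("epoch %d: train loss %.5f", epoch, history.train_loss[-1])
    return model, history


# --------------------------------------------------------------------------
# hyperparameter tuning (sequential model-based optimization)
# --------------------------------------------------------------------------

def _sample_space(space: dict, rng: np.random.Generator) -> dict[str, object]:
    out: dict[str, object] = {}
    for name, entry in space.items():
        if isinstance(entry, (list,)):
            out[name] = entry[int(rng.integers(0, len(entry)))]
        elif isinstance(entry, tuple):
            low, high = entry[0], entry[1]
            log = len(entry) > 2 and entry[2] == "log"
            if log:
                value = float(np.exp(rng.uniform(np.log(low), np.log(high))))
            else:
                value = float(rng.uniform(low, high))
            if isinstance(low, int) and isinstance(high, int) and not log:
                value = int(round(value))
            out[name] = value
        else:
            out[name] = entry
    return out


def _encode_point(point: dict, space: dict) -> list[float]:
    coords = []
    for name, entry in space.items():
        if isinstance(entry, tuple):
            low, high = entry[0], entry[1]
            log = len(entry) > 2 and entry[2] == "log"
            value = float(point[name])
            if log:
                coords.append(
                    (np.log(value) - np.log(low)) / (np.log(high) - np.log(low))
                )
            elif high > low:
                coords.append((value - low) / (high - low))
        elif isinstance(entry, list) and len(entry) > 1:
            coords.append(entry.index(point[name]) / (len(entry) - 1))
    return coords


def tune_hyperparameters(
    train_samples: list[TrainingSample],
    search_space: dict | None = None,
    n_evals: int = 20,
    seed: int = 0,
    tune_epochs: int = 2,
    return_trials: bool = False,
):
    """Bayesian (sequential model-based) search over the config space.

    Each of the ``n_evals`` evaluations trains a short model on 80% of
    ``train_samples`` and scores it by the validation loss on the other
    20%. The first third of the budget explores at random; subsequent
    points maximize expected improvement under a Gaussian-process
    surrogate. Returns the best-scoring :class:`ModelConfig` (or
    ``(config, trials)`` with ``return_trials``).
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    from .encoding import build_vocabulary, encode_dataset
    from .sampling import build_last_tool_index

    space = dict(DEFAULT_SEARCH_SPACE) if search_space is None else dict(search_space)
    if not space:
        raise ValidationError("empty search space")
    unknown = set(space) - set(ModelConfig.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"unknown hyperparameters {sorted(unknown)}")

    rng = np.random.default_rng(_derive_seed(seed, 11))
    vocab = build_vocabulary(train_samples)
    split = split_train_test(train_samples, fraction=0.8, seed=_derive_seed(seed, 12))
    sub_train = encode_dataset(split.train, vocab)
    val = encode_dataset(split.test, vocab)
    index = build_last_tool_index(split.train, vocab)
    uniform = ToolWeights().vector(vocab.size)
    y_val = val.combined_labels.astype(np.float64)

    def evaluate(point: dict) -> float:
        cfg = replace(
            ModelConfig(),
            **point,
            epochs=tune_epochs,
            max_len=sub_train.sequences.shape[1],
        )
        model = build_model(cfg, vocab, seed=_derive_seed(seed, 13))
        train(model, sub_train, sampler=index, seed=_derive_seed(seed, 14))
        probs = model.predict(val.sequences)
        return weighted_crossentropy(y_val, probs, uniform)

    trials: list[tuple[dict, float]] = []
    n_init = min(n_evals, max(3, n_evals // 3))
    for _ in range(n_init):
        point = _sample_space(space, rng)
        trials.append((point, evaluate(point)))

    while len(trials) < n_evals:
        xs = np.array([_encode_point(p, space) for p, _ in trials])
        ys = np.array([s for _, s in trials])
        if xs.size == 0:  # fully degenerate space: nothing to model
            point = _sample_space(space, rng)
        else:
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5), normalize_y=True, random_state=0
            )
            gp.fit(xs, ys)
            candidates = [_sample_space(space, rng) for _ in range(128)]
            cx = np.array([_encode_point(p, space) for p in candidates])
            mu, sd = gp.predict(cx, return_std=True)
            best = ys.min()
            sd = np.maximum(sd, 1e-12)
            z = (best - mu) / sd
            ei = (best - mu) * ndtr(z) + sd * np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)
            point = candidates[int(np.argmax(ei))]
        trials.append((point, evaluate(point)))

    best_point, _ = min(trials, key=lambda t: t[1])
    best_config = replace(ModelConfig(), **best_point)
    if return_trials:
        return best_config, trials
    return best_config


# --------------------------------------------------------------------------
# model store (HDF5)
# --------------------------------------------------------------------------

_STORE_GROUPS = ("network", "vocabulary", "tool_weights")


def save_model(model: RecommenderModel, path) -> None:
    """Persist network parameters + config, tool dictionary and weights."""
    if model.vocabulary is None:
        raise ValidationError("cannot save a model without its vocabulary")
    vocab = model.vocabulary
    id_of = vocab.id_of
    tools = [id_of[i] for i in range(1, vocab.size + 1)]
    with h5py.File(path, "w") as store:
        net = store.create_group("network")
        net.attrs["config"] = json.dumps(asdict(model.config))
        for name, arr in model.params.items():
            net.create_dataset(name, data=arr)
        voc = store.create_group("vocabulary")
        voc.create_dataset("tools", data=np.array(tools, dtype=h5py.string_dtype()))
        if model.shared_tools is not None:
            flags = np.array([t in model.shared_tools for t in tools], dtype=np.uint8)
            voc.create_dataset("shared_capable", data=flags)
        weights = model.tool_weights or ToolWeights()
        tw = store.create_group("tool_weights")
        tw.attrs["default_weight"] = weights.default_weight
        indices = np.array(sorted(weights.weight_of), dtype=np.int64)
        tw.create_dataset("indices", data=indices)
        tw.create_dataset(
            "values", data=np.array([weights.weight_of[i] for i in indices])
        )


def load_model(path) -> RecommenderModel:
    """Reconstruct a model whose predictions match the saved one exactly."""
    with h5py.File(path, "r") as store:
        for group in _STORE_GROUPS:
            if group not in store:
                raise CorruptStoreError(f"store is missing group {group!r}")
        net = store["network"]
        config = ModelConfig(**json.loads(net.attrs["config"]))
        params = {name: np.asarray(net[name][...]) for name in net}
        voc = store["vocabulary"]
        tools = [t.decode() for t in voc["tools"][...]]
        vocabulary = ToolVocabulary(index_of={t: i + 1 for i, t in enumerate(tools)})
        shared_tools = None
        if "shared_capable" in voc:
            flags = voc["shared_capable"][...]
            shared_tools = frozenset(t for t, f in zip(tools, flags) if f)
        tw = store["tool_weights"]
        weight_of = {
            int(i): float(v) for i, v in zip(tw["indices"][...], tw["values"][...])
        }
        weights = ToolWeights(
            weight_of=weight_of, default_weight=float(tw.attrs["default_weight"])
        )
    if params["out_b"].shape[0] != vocabulary.size:
        raise CorruptStoreError("dense layer width disagrees with the dictionary")
    return RecommenderModel(
        config=config,
        vocab_size=vocabulary.size,
        vocabulary=vocabulary,
        tool_weights=weights,
        shared_tools=shared_tools,
        params=params,
    )
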