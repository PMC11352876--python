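"""A gated recurrent (LSTM) binary sequence classifier built on numpy.

The cell follows the standard formulation: input/forget/output gates are
sigmoid-activated affine maps of the current input and previous hidden
state, the cell candidate is tanh-activated, and the hidden state is the
output gate times the squashed cell state.  Training minimizes softmax
cross-entropy by full backpropagation through time with global gradient-norm
clipping, inverted dropout on the hidden-to-readout path, and either
adaptive-moment ("adam", default) or plain stochastic gradient descent
updates.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError
from .optim import SearchSpace

__all__ = [
    "LSTMConfig",
    "LSTMModel",
    "TrainReport",
    "init_model",
    "cell_forward",
    "train",
    "predict",
    "cv_fitness",
    "save_model",
    "load_model",
    "export_train_log",
]

N_CLASSES = 2


@dataclass
class LSTMConfig:
    """Training hyperparameters.

    Defaults for ``gradient_threshold``, ``learning_rate``, ``hidden_units``
    and ``dropout`` follow the tuning framework's reference values; epochs
    and batch size are desk-scale choices.
    """

    hidden_units: int = 100
    learning_rate: float = 1e-4
    dropout: float = 0.5
    gradient_threshold: float = 0.01
    epochs: int = 30
    batch_size: int = 16
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ConfigurationError("hidden_units must be >= 1")
        if not (self.learning_rate > 0):
            raise ConfigurationError("learning_rate must be positive")
        if not (0 <= self.dropout < 1):
            raise ConfigurationError("dropout must lie in [0, 1)")
        if not (self.gradient_threshold > 0):
            raise ConfigurationError("gradient_threshold must be positive")
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class LSTMModel:
    """Gate weights (order: input, forget, output, candidate) and readout."""

    wx: np.ndarray  # (n_features, 4H)
    wh: np.ndarray  # (H, 4H)
    b: np.ndarray  # (4H,)
    wo: np.ndarray  # (H, 2)
    bo: np.ndarray  # (2,)
    config: LSTMConfig

    @property
    def hidden_units(self) -> int:
        return self.wh.shape[0]

    @property
    def n_features(self) -> int:
        return self.wx.shape[0]

    def params(self) -> list[np.ndarray]:
        return [self.wx, self.wh, self.b, self.wo, self.bo]


@dataclass
class TrainReport:
    epoch_losses: list[float] = field(default_factory=list)
    final_train_accuracy: float = 0.0
    n_updates: int = 0
    seed: int = 0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_model(n_features: int, config: LSTMConfig) -> LSTMModel:
    """Seeded small-uniform initialization (readout starts near zero so the
    initial loss of a balanced task sits at ~ln 2)."""
    rng = np.random.default_rng(config.seed)
    h = config.hidden_units
    scale = 0.2 / math.sqrt(max(n_features, h))
    wx = rng.uniform(-scale, scale, size=(n_features, 4 * h))
    wh = rng.uniform(-scale, scale, size=(h, 4 * h))
    b = np.zeros(4 * h)
    wo = rng.uniform(-scale, scale, size=(h, N_CLASSES)) * 0.1
    bo = np.zeros(N_CLASSES)
    return LSTMModel(wx, wh, b, wo, bo, config)


def cell_forward(
    x_t: np.ndarray, h: np.ndarray, c: np.ndarray, model: LSTMModel
) -> tuple[np.ndarray, np.ndarray]:
    """One gated update; accepts (F,)/(H,) vectors or (B, F)/(B, H) batches."""
    squeeze = x_t.ndim == 1
    x_t = np.atleast_2d(x_t)
    h = np.atleast_2d(h)
    c = np.atleast_2d(c)
    hdim = model.hidden_units
    if x_t.shape[1] != model.n_features or h.shape[1] != hdim or c.shape[1] != hdim:
        raise ConfigurationError(
            f"shape mismatch: x{x_t.shape} h{h.shape} c{c.shape} for model "
            f"({model.n_features} features, {hdim} hidden)"
        )
    z = x_t @ model.wx + h @ model.wh + model.b
    i = _sigmoid(z[:, 0 * hdim:1 * hdim])
    f = _sigmoid(z[:, 1 * hdim:2 * hdim])
    o = _sigmoid(z[:, 2 * hdim:3 * hdim])
    g = np.tanh(z[:, 3 * hdim:4 * hdim])
    c_new = f * c + i * g
    h_new = o * np.tanh(c_new)
    if squeeze:
        return h_new[0], c_new[0]
    return h_new, c_new


def _forward_sequence(x: np.ndarray, model: LSTMModel) -> tuple[np.ndarray, list]:
    """Run a (B, T, F) batch through the cell; returns final hidden state
    and per-step caches for BPTT."""
    batch, steps, _ = x.shape
    hdim = model.hidden_units
    h = np.zeros((batch, hdim))
    c = np.zeros((batch, hdim))
    caches = []
    for t in range(steps):
        x_t = x[:, t, :]
        z = x_t @ model.wx + h @ model.wh + model.b
        i = _sigmoid(z[:, :hdim])
        f = _sigmoid(z[:, hdim:2 * hdim])
        o = _sigmoid(z[:, 2 * hdim:3 * hdim])
        g = np.tanh(z[:, 3 * hdim:])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        caches.append((x_t, h, c, i, f, o, g, tanh_c))
        h = o * tanh_c
        c = c_new
    return h, caches


def _backward(
    dh: np.ndarray, caches: list, model: LSTMModel
) -> list[np.ndarray]:
    hdim = model.hidden_units
    d_wx = np.zeros_like(model.wx)
    d_wh = np.zeros_like(model.wh)
    d_b = np.zeros_like(model.b)
    dc = np.zeros_like(dh)
    for x_t, h_prev, c_prev, i, f, o, g, tanh_c in reversed(caches):
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), dg * (1 - g**2)],
            axis=1,
        )
        d_wx += x_t.T @ dz
        d_wh += h_prev.T @ dz
        d_b += dz.sum(axis=0)
        dh = dz @ model.wh.T
        dc = dc * f
    return [d_wx, d_wh, d_b]


def _clip_global_norm(grads: list[np.ndarray], threshold: float) -> float:
    total = math.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total > threshold and total > 0:
        scale = threshold / total
        for g in grads:
            g *= scale
        return threshold
    return total


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Accept (X, y) with X a (N, T, F) array or list of (T, F) sequences."""
    x, y = dataset
    if isinstance(x, np.ndarray) and x.ndim == 3:
        arr = np.asarray(x, dtype=float)
    else:
        seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in x]
        if not seqs:
            raise ConfigurationError("empty dataset")
        shape = seqs[0].shape
        if any(s.shape != shape for s in seqs):
            raise ConfigurationError("all sequences must share one (T, F) shape")
        arr = np.stack(seqs)
    y = np.asarray(y, dtype=int)
    if y.shape != (arr.shape[0],):
        raise ConfigurationError("labels must align with sequences")
    return arr, y


def train(
    dataset: tuple,
    config: LSTMConfig,
    grad_hook: Callable[[float], None] | None = None,
) -> tuple[LSTMModel, TrainReport]:
    """Mini-batch training of the softmax cross-entropy loss.

    ``dataset`` is ``(sequences, labels)`` with integer labels in {0, 1}
    (1 = positive/seizure class).  Gradients are clipped to
    ``gradient_threshold`` global norm before each update; ``grad_hook``
    (if given) receives the post-clip norm of every update.  With
    ``epochs = 0`` the seeded initialization is returned untouched with an
    empty loss history.
    """
    x, y = _as_xy(dataset)
    classes = np.unique(y)
    if classes.size < 2:
        raise ConfigurationError("training requires at least 2 classes")
    if not np.isin(classes, [0, 1]).all():
        raise ConfigurationError("labels must be 0/1 integers")
    n, _, n_features = x.shape
    model = init_model(n_features, config)
    rng = np.random.default_rng(config.seed + 1)
    report = TrainReport(seed=config.seed)

    if config.optimizer == "adam":
        m_state = [np.zeros_like(p) for p in model.params()]
        v_state = [np.zeros_like(p) for p in model.params()]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

    keep = 1.0 - config.dropout
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            h, caches = _forward_sequence(xb, model)
            if config.dropout > 0:
                mask = (rng.random(h.shape) < keep) / keep
            else:
                mask = np.ones_like(h)
            h_drop = h * mask
            logits = h_drop @ model.wo + model.bo
            shifted = logits - logits.max(axis=1, keepdims=True)
            expl = np.exp(shifted)
            probs = expl / expl.sum(axis=1, keepdims=True)
            batch = xb.shape[0]
            loss = -float(np.mean(np.log(probs[np.arange(batch), yb] + 1e-300)))
            if not math.isfinite(loss):
                raise ConfigurationError("non-finite training loss; aborting")
            epoch_loss += loss * batch

            dlogits = probs.copy()
            dlogits[np.arange(batch), yb] -= 1.0
            dlogits /= batch
            d_wo = h_drop.T @ dlogits
            d_bo = dlogits.sum(axis=0)
            dh = (dlogits @ model.wo.T) * mask
            d_wx, d_wh, d_b = _backward(dh, caches, model)
            grads = [d_wx, d_wh, d_b, d_wo, d_bo]
            norm = _clip_global_norm(grads, config.gradient_threshold)
            if grad_hook is not None:
                grad_hook(norm)

            params = model.params()
            if config.optimizer == "adam":
                step += 1
                for p, g, m_s, v_s in zip(params, grads, m_state, v_state):
                    m_s += (1 - beta1) * (g - m_s)
                    v_s += (1 - beta2) * (g * g - v_s)
                    m_hat = m_s / (1 - beta1**step)
                    v_hat = v_s / (1 - beta2**step)
                    p -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            else:
                for p, g in zip(params, grads):
                    p -= config.learning_rate * g
            report.n_updates += 1
        report.epoch_losses.append(epoch_loss / n)

    pred, _ = predict(model, x)
    report.final_train_accuracy = float(np.mean(pred == y))
    return model, report


def predict(
    model: LSTMModel, sequences: np.ndarray | Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic inference (dropout disabled).

    Returns ``(labels, scores)`` where scores are the per-class softmax
    probabilities (rows sum to 1).  A tie at probability 0.5 resolves to
    the negative class.
    """
    if isinstance(sequences, np.ndarray) and sequences.ndim == 3:
        x = np.asarray(sequences, dtype=float)
    else:
        x = np.stack([np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences])
    if x.shape[2] != model.n_features:
        raise ConfigurationError(
            f"feature width {x.shape[2]} does not match model ({model.n_features})"
        )
    h, _ = _forward_sequence(x, model)
    logits = h @ model.wo + model.bo
    shifted = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(shifted)
    probs = expl / expl.sum(axis=1, keepdims=True)
    labels = (probs[:, 1] > 0.5).astype(int)
    return labels, probs


_WEIGHT_NAMES = ("wx", "wh", "b", "wo", "bo")


def save_model(model: LSTMModel, path) -> None:
    """Write the model as one JSON archive: config manifest plus weights."""
    import dataclasses
    import json
    from pathlib import Path

    payload = {
        "config": dataclasses.asdict(model.config),
        "weights": {name: getattr(model, name).tolist() for name in _WEIGHT_NAMES},
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path) -> LSTMModel:
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    config = LSTMConfig(**payload["config"])
    weights = {name: np.asarray(payload["weights"][name], dtype=float)
               for name in _WEIGHT_NAMES}
    return LSTMModel(config=config, **weights)


def export_train_log(report: TrainReport, path) -> None:
    """Write the per-epoch loss history as a TSV table."""
    from pathlib import Path

    lines = ["epoch\tloss"]
    lines += [f"{i}\t{loss!r}" for i, loss in enumerate(report.epoch_losses, start=1)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def cv_fitness(
    config_position: np.ndarray,
    space: SearchSpace,
    dataset: tuple,
    k_folds: int,
    seed: int,
    base_config: LSTMConfig | None = None,
) -> float:
    """Stratified k-fold validation error of a decoded hyperparameter point.

    Decodes ``config_position`` through ``space``, trains one model per
    fold, and returns ``1 - mean validation accuracy`` (in [0, 1]).
    Deterministic for a fixed position and seed, as required for coherent
    optimization.
    """
    if k_folds < 2:
        raise ConfigurationError("k_folds must be >= 2")
    x, y = _as_xy(dataset)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k_folds:
        raise ConfigurationError(
            f"cannot stratify {k_folds} folds with class counts {counts.tolist()}"
        )
    decoded = space.decode(config_position)
    base = base_config if base_config is not None else LSTMConfig()
    config = LSTMConfig(
        hidden_units=decoded["hidden_units"],
        learning_rate=decoded["learning_rate"],
        dropout=decoded["dropout"],
        gradient_threshold=base.gradient_threshold,
        epochs=base.epochs,
        batch_size=base.batch_size,
        optimizer=base.optimizer,
        seed=seed,
    )
    splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accuracies = []
    for train_idx, val_idx in splitter.split(x, y):
        model, _ = train((x[train_idx], y[train_idx]), config)
        pred, _ = predict(model, x[val_idx])
        accuracies.append(float(np.mean(pred == y[val_idx])))
    return 1.0 - float(np.mean(accuracies))
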