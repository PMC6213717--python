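"""The 10-20-20-2 tanh network behind the meta-predictor.

A small fully connected feed-forward network: ten inputs (the encoded
vote features), two hidden layers of twenty nodes, two output nodes.
Every node applies the hyperbolic tangent; the two output activations are
then passed through a softmax so the pair forms a disorder/structure
probability distribution.  Training is mini-batch gradient descent with
momentum on the cross-entropy, with early stopping monitored on a
dedicated hold-out ("stop") set: the returned weights are the snapshot
with the best stop-set loss.

Input features are standardized with training-set statistics stored in
the model, since the encoder's a/d features live on heterogeneous scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

LAYER_SIZES = (10, 20, 20, 2)


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainConfig:
    """Training hyperparameters (the architecture itself is fixed)."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 128
    max_epochs: int = 2000
    patience: int = 50
    seed: int = 0
    class_weights: tuple[float, float] | None = None  # (w_neg, w_pos)

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience) <= 0:
            raise ValueError("learning rate, batch size, epochs and patience "
                             "must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class NetworkModel:
    """Weights, feature standardization and training metadata."""

    weights: list[np.ndarray]   # W per layer, shapes (10,20), (20,20), (20,2)
    biases: list[np.ndarray]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    seed: int = 0
    epochs_run: int = 0
    stop_reason: str = "untrained"

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Probability pairs (P(structured), P(disordered)) per row."""
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != LAYER_SIZES[0]:
            raise ValueError(
                f"expected (n, {LAYER_SIZES[0]}) inputs, got {X.shape}")
        h = (X - self.feature_mean) / self.feature_std
        for W, b in zip(self.weights, self.biases):
            h = np.tanh(h @ W + b)
        return _softmax(h)

    def predict_proba_disorder(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[:, 1]

    def to_json(self, path, extra: dict | None = None) -> None:
        obj = {
            "layer_sizes": list(LAYER_SIZES),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "seed": self.seed,
            "epochs_run": self.epochs_run,
            "stop_reason": self.stop_reason,
        }
        if extra:
            obj.update(extra)
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> tuple["NetworkModel", dict]:
        with open(path) as fh:
            obj = json.load(fh)
        if tuple(obj["layer_sizes"]) != LAYER_SIZES:
            raise ValueError(f"unsupported architecture {obj['layer_sizes']}")
        model = cls(
            weights=[np.array(w) for w in obj["weights"]],
            biases=[np.array(b) for b in obj["biases"]],
            feature_mean=np.array(obj["feature_mean"]),
            feature_std=np.array(obj["feature_std"]),
            seed=obj.get("seed", 0),
            epochs_run=obj.get("epochs_run", 0),
            stop_reason=obj.get("stop_reason", ""),
        )
        extra = {k: v for k, v in obj.items()
                 if k not in {"layer_sizes", "weights", "biases", "feature_mean",
                              "feature_std", "seed", "epochs_run", "stop_reason"}}
        return model, extra


def _init_params(rng: np.random.Generator) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for fan_in, fan_out in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward_raw(weights, biases, Xs):
    """Forward pass on already-standardized inputs, keeping activations."""
    acts = [Xs]
    h = Xs
    for W, b in zip(weights, biases):
        h = np.tanh(h @ W + b)
        acts.append(h)
    return _softmax(acts[-1]), acts


def loss_and_grads(weights, biases, Xs, Y, sample_weight=None):
    """Mean weighted cross-entropy and its gradients.

    ``Y`` is one-hot ``(n, 2)``; ``Xs`` is standardized input.  Used both
    by the trainer and by finite-difference gradient checks.
    """
    n = Xs.shape[0]
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    wsum = w.sum()
    P, acts = _forward_raw(weights, biases, Xs)
    eps = 1e-12
    loss = float(-(w * (Y * np.log(P + eps)).sum(axis=1)).sum() / wsum)

    gW = [np.zeros_like(W) for W in weights]
    gb = [np.zeros_like(b) for b in biases]
    # output: softmax(tanh(z)); dL/d tanh(z) = P - Y, then through tanh
    delta = (P - Y) * (w / wsum)[:, None]
    for layer in range(len(weights) - 1, -1, -1):
        delta = delta * (1.0 - acts[layer + 1] ** 2)  # tanh'
        gW[layer] = acts[layer].T @ delta
        gb[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = delta @ weights[layer].T
    return loss, gW, gb


def _stop_loss(weights, biases, Xs, Y, sample_weight=None):
    n = Xs.shape[0]
    w = np.ones(n) if sample_weight is None else sample_weight
    P, _ = _forward_raw(weights, biases, Xs)
    return float(-(w * (Y * np.log(P + 1e-12)).sum(axis=1)).sum() / w.sum())


def train(train_X, train_y, stop_X, stop_y, config: TrainConfig,
          history_out: list | None = None) -> NetworkModel:
    """Fit the network; early stopping on the stop set.

    Returns the weight snapshot with the lowest stop-set loss seen during
    training.  Identical seed, config and data produce identical models.
    ``history_out``, when given, collects the stop-set loss per epoch.
    """
    train_X = np.asarray(train_X, float)
    train_y = np.asarray(train_y, int)
    stop_X = np.asarray(stop_X, float)
    stop_y = np.asarray(stop_y, int)
    if train_X.ndim != 2 or train_X.shape[1] != LAYER_SIZES[0]:
        raise ValueError(f"expected (n, {LAYER_SIZES[0]}) features")
    classes = np.unique(train_y)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")

    mean = train_X.mean(axis=0)
    std = train_X.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    Xs = (train_X - mean) / std
    Ss = (stop_X - mean) / std
    Y = np.eye(2)[train_y]
    Ystop = np.eye(2)[stop_y]

    sw = None
    stop_sw = None
    if config.class_weights is not None:
        cw = np.asarray(config.class_weights, float)
        sw = cw[train_y]
        stop_sw = cw[stop_y]

    rng = np.random.default_rng(config.seed)
    weights, biases = _init_params(rng)
    vel_W = [np.zeros_like(W) for W in weights]
    vel_b = [np.zeros_like(b) for b in biases]

    n = Xs.shape[0]
    best_loss = np.inf
    best = ([W.copy() for W in weights], [b.copy() for b in biases])
    best_epoch = 0
    stop_reason = "max_epochs"
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            bw = None if sw is None else sw[idx]
            loss, gW, gb = loss_and_grads(weights, biases, Xs[idx], Y[idx], bw)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            for k in range(len(weights)):
                vel_W[k] = config.momentum * vel_W[k] - config.learning_rate * gW[k]
                vel_b[k] = config.momentum * vel_b[k] - config.learning_rate * gb[k]
                weights[k] += vel_W[k]
                biases[k] += vel_b[k]
        s_loss = _stop_loss(weights, biases, Ss, Ystop, stop_sw)
        if history_out is not None:
            history_out.append(s_loss)
        if s_loss < best_loss - 1e-9:
            best_loss = s_loss
            best = ([W.copy() for W in weights], [b.copy() for b in biases])
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            stop_reason = f"early_stop(no improvement for {config.patience} epochs)"
            break

    return NetworkModel(
        weights=best[0], biases=best[1], feature_mean=mean, feature_std=std,
        seed=config.seed, epochs_run=epoch, stop_reason=stop_reason,
    )


def forward(model: NetworkModel, encoded_batch) -> np.ndarray:
    """Probability pairs for a batch of encoded 10-vectors."""
    return model.forward(np.asarray(encoded_batch, float))


def predict(model: NetworkModel, dataset, thresholds, call_cutoff: float = 0.5):
    """Encode a dataset, run the network, and threshold into binary calls."""
    from .encoder import encode_matrix

    X, _ = dataset.stacked()
    feats, _ = encode_matrix(X, thresholds)
    probs = model.predict_proba_disorder(feats)
    calls = (probs >= call_cutoff).astype(int)
    return probs, calls
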