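"""The seven-layer classifier on pair-similarity vectors, and transfer learning.

The network has one input layer (the 231-dimensional pair-similarity
vector), five fully connected ReLU hidden layers with dropout, and an
output layer of two independent sigmoid units trained against one-hot
targets with binary cross-entropy; the reported score is the positive-class
unit, a probability that the window is a genuine binding phosphosite.
Training is plain stochastic gradient descent with momentum and L2 weight
decay, fully reproducible from the configuration seed.  Family and cluster
models are obtained by transfer learning: parameters are initialized from
the parent model and fine-tuned on the smaller child data at a reduced
learning rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import roc_auc, stratified_folds

N_HIDDEN_LAYERS = 5
_CLIP_NORM = 5.0


def relu(x):
    """max(x, 0), elementwise."""
    return np.maximum(x, 0.0)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass(frozen=True)
class DNNConfig:
    """Hyperparameters of the seven-layer network.

    ``output_units=2`` gives the two-sigmoid output layer; a single-unit
    variant is selectable.  ``patience`` epochs without validation-AUC
    improvement stop training early (0 disables early stopping).
    """

    hidden_layer_sizes: tuple = (128, 64, 32, 16, 8)
    dropout_ratio: float = 0.1
    learning_rate: float = 0.02
    momentum: float = 0.9
    batch_size: int = 32
    l2_strength: float = 1e-4
    epochs: int = 150
    seed: int = 0
    output_units: int = 2
    validation_fraction: float = 0.1
    patience: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_layer_sizes) != N_HIDDEN_LAYERS:
            raise ValueError(
                f"exactly {N_HIDDEN_LAYERS} hidden layers are required "
                f"(input + {N_HIDDEN_LAYERS} hidden + output = 7 layers), "
                f"got {len(self.hidden_layer_sizes)}")
        if any(int(h) <= 0 for h in self.hidden_layer_sizes):
            raise ValueError("hidden layer sizes must be positive")
        if not 0 <= self.dropout_ratio < 1:
            raise ValueError("dropout_ratio must be in [0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("batch_size must be positive and epochs non-negative")
        if self.l2_strength < 0:
            raise ValueError("l2_strength must be non-negative")
        if self.output_units not in (1, 2):
            raise ValueError("output_units must be 1 or 2")
        object.__setattr__(self, "hidden_layer_sizes",
                           tuple(int(h) for h in self.hidden_layer_sizes))

    def layer_widths(self, input_width: int) -> list[int]:
        return [input_width, *self.hidden_layer_sizes, self.output_units]

    def parameter_count(self, input_width: int) -> int:
        w = self.layer_widths(input_width)
        return sum(a * b + b for a, b in zip(w[:-1], w[1:]))


class TrainedModel:
    """A trained network: configuration plus layer weight/bias arrays."""

    def __init__(self, config: DNNConfig, weights: list[np.ndarray],
                 biases: list[np.ndarray], hierarchy_node=None,
                 parent_model: "TrainedModel | None" = None,
                 input_center: np.ndarray | None = None,
                 input_scale: np.ndarray | None = None) -> None:
        self.config = config
        self.weights = weights
        self.biases = biases
        self.hierarchy_node = hierarchy_node
        self.parent_model = parent_model
        # input standardization learned from the training data; part of the
        # model so inference sees the same feature scale as training
        self.input_center = input_center
        self.input_scale = input_scale

    @property
    def input_width(self) -> int:
        return self.weights[0].shape[0]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        if self.input_center is None:
            return X
        return (X - self.input_center) / self.input_scale

    def _forward(self, X: np.ndarray) -> np.ndarray:
        h = self.standardize(X)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = relu(h @ W + b)
        return h @ self.weights[-1] + self.biases[-1]

    def predict_proba(self, X) -> np.ndarray:
        """Positive-class probability per row; dropout is off at inference."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.input_width:
            raise ValueError(f"input width {X.shape[1]} != model width {self.input_width}")
        z = self._forward(X)
        p = sigmoid(z)
        # keep probabilities strictly inside (0, 1) despite float saturation
        return np.clip(p[:, -1], 1e-12, 1.0 - 1e-12)

    def clone(self) -> "TrainedModel":
        return TrainedModel(self.config, [w.copy() for w in self.weights],
                            [b.copy() for b in self.biases],
                            self.hierarchy_node, self.parent_model,
                            None if self.input_center is None else self.input_center.copy(),
                            None if self.input_scale is None else self.input_scale.copy())

    def to_dict(self) -> dict:
        return {
            "format": "gpspbs-dnn/1",
            "config": {**self.config.__dict__,
                       "hidden_layer_sizes": list(self.config.hidden_layer_sizes)},
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "input_center": None if self.input_center is None
            else self.input_center.tolist(),
            "input_scale": None if self.input_scale is None
            else self.input_scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        cfg = dict(d["config"])
        cfg["hidden_layer_sizes"] = tuple(cfg["hidden_layer_sizes"])
        center = d.get("input_center")
        scale = d.get("input_scale")
        return cls(DNNConfig(**cfg),
                   [np.array(w, float) for w in d["weights"]],
                   [np.array(b, float) for b in d["biases"]],
                   input_center=None if center is None else np.array(center, float),
                   input_scale=None if scale is None else np.array(scale, float))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def predict_proba(model: TrainedModel, vectors) -> np.ndarray:
    return model.predict_proba(vectors)


def _init_params(widths: list[int], rng: np.random.Generator):
    weights, biases = [], []
    for a, b in zip(widths[:-1], widths[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)))
        biases.append(np.zeros(b))
    return weights, biases


def _one_hot(y: np.ndarray, units: int) -> np.ndarray:
    if units == 1:
        return y[:, None].astype(float)
    return np.column_stack([1.0 - y, y.astype(float)])


def _sgd_train(model: TrainedModel, X: np.ndarray, y: np.ndarray,
               config: DNNConfig, rng: np.random.Generator) -> TrainedModel:
    """In-place SGD-with-momentum training of ``model``; returns it."""
    n = len(X)
    Xs = model.standardize(X)
    # hold out a stratified validation slice for early stopping when feasible
    use_es = (config.patience > 0 and config.validation_fraction > 0
              and min(np.sum(y == 1), np.sum(y == 0)) * config.validation_fraction >= 1)
    if use_es:
        order = rng.permutation(n)
        val_idx, train_idx = [], []
        for cls in (0, 1):
            members = [i for i in order if y[i] == cls]
            n_val = max(1, int(round(len(members) * config.validation_fraction)))
            val_idx += members[:n_val]
            train_idx += members[n_val:]
        Xtr, ytr = Xs[train_idx], y[train_idx]
        Xval, yval = X[val_idx], y[val_idx]  # raw; predict_proba standardizes
    else:
        Xtr, ytr = Xs, y

    T = _one_hot(ytr, config.output_units)
    vel_w = [np.zeros_like(w) for w in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    drop = config.dropout_ratio
    best_auc, best_params, stale = -np.inf, None, 0

    for _epoch in range(config.epochs):
        order = rng.permutation(len(Xtr))
        for lo in range(0, len(Xtr), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb, tb = Xtr[idx], T[idx]
            # forward with dropout on the hidden activations
            hs, zs, masks = [xb], [], []
            h = xb
            for li, (W, b) in enumerate(zip(model.weights, model.biases)):
                z = h @ W + b
                zs.append(z)
                if li < len(model.weights) - 1:
                    h = relu(z)
                    if drop > 0:
                        mask = (rng.random(h.shape) >= drop) / (1.0 - drop)
                        h = h * mask
                        masks.append(mask)
                    else:
                        masks.append(None)
                    hs.append(h)
            p = sigmoid(zs[-1])
            dz = (p - tb) / len(xb)  # BCE + sigmoid gradient
            grads_w, grads_b = [], []
            for li in range(len(model.weights) - 1, -1, -1):
                grads_w.append(hs[li].T @ dz + config.l2_strength * model.weights[li])
                grads_b.append(dz.sum(axis=0))
                if li > 0:
                    dh = dz @ model.weights[li].T
                    if masks[li - 1] is not None:
                        dh = dh * masks[li - 1]
                    dz = dh * (zs[li - 1] > 0)
            grads_w.reverse()
            grads_b.reverse()
            # global-norm clipping keeps SGD stable on hard batches
            norm = np.sqrt(sum(float(np.sum(g * g))
                               for g in grads_w + grads_b))
            if norm > _CLIP_NORM:
                factor = _CLIP_NORM / norm
                grads_w = [g * factor for g in grads_w]
                grads_b = [g * factor for g in grads_b]
            for li in range(len(model.weights)):
                vel_w[li] = config.momentum * vel_w[li] \
                    - config.learning_rate * grads_w[li]
                vel_b[li] = config.momentum * vel_b[li] \
                    - config.learning_rate * grads_b[li]
                model.weights[li] += vel_w[li]
                model.biases[li] += vel_b[li]
        if use_es:
            auc, _ = roc_auc(model.predict_proba(Xval), yval)
            if auc > best_auc + 1e-12:
                best_auc, stale = auc, 0
                best_params = ([w.copy() for w in model.weights],
                               [b.copy() for b in model.biases])
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if use_es and best_params is not None:
        model.weights, model.biases = best_params
    return model


def train_dnn(X, y, config: DNNConfig | None = None,
              hierarchy_node=None) -> TrainedModel:
    """Train the network from scratch on encoded vectors X with 0/1 labels y."""
    config = config or DNNConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least 2 items per class")
    rng = np.random.default_rng(config.seed)
    weights, biases = _init_params(config.layer_widths(X.shape[1]), rng)
    center = X.mean(axis=0)
    scale = np.maximum(X.std(axis=0), 1e-8)
    model = TrainedModel(config, weights, biases, hierarchy_node=hierarchy_node,
                         input_center=center, input_scale=scale)
    return _sgd_train(model, X, y, config, rng)


def fine_tune(parent: TrainedModel, X, y, *, epochs: int | None = None,
              lr_scale: float = 0.1, seed: int | None = None,
              hierarchy_node=None, **config_overrides) -> TrainedModel:
    """Transfer learning: start from the parent's parameters, train on child data.

    The child inherits the parent configuration with a learning rate reduced
    by ``lr_scale``.  With ``epochs=0`` the returned model's predictions are
    identical to the parent's.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if len(X) == 0:
        raise ValueError("child data is empty")
    if X.shape[1] != parent.input_width:
        raise ValueError(f"child input width {X.shape[1]} != parent width "
                         f"{parent.input_width}")
    config = replace(parent.config,
                     learning_rate=parent.config.learning_rate * lr_scale,
                     epochs=parent.config.epochs if epochs is None else epochs,
                     seed=parent.config.seed if seed is None else seed,
                     **config_overrides)
    child = parent.clone()
    child.config = config
    child.parent_model = parent
    child.hierarchy_node = hierarchy_node
    if config.epochs == 0:
        return child
    if np.sum(y == 1) < 1 or np.sum(y == 0) < 1:
        raise ValueError("child data must contain both classes")
    rng = np.random.default_rng(config.seed)
    return _sgd_train(child, X, y, config, rng)


def hyperparameter_search(X, y, grid, folds: int = 10, seed: int = 0,
                          ) -> tuple[DNNConfig, float]:
    """Pick the grid configuration maximizing mean k-fold CV AUC.

    Ties break toward the smaller parameter count, then grid order.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    assignment = stratified_folds(y, folds, seed)
    best = None  # (-auc, n_params, order)
    for order, config in enumerate(grid):
        aucs = []
        for f in range(folds):
            tr, te = assignment != f, assignment == f
            model = train_dnn(X[tr], y[tr], config)
            auc, _ = roc_auc(model.predict_proba(X[te]), y[te])
            aucs.append(auc)
        mean_auc = float(np.mean(aucs))
        key = (-mean_auc, config.parameter_count(X.shape[1]), order)
        if best is None or key < best[0]:
            best = (key, config, mean_auc)
    return best[1], best[2]
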