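"""Feed-forward binary classifier trained with a fixed recipe.

Architecture: ``n_layers`` hidden layers of ``hidden_units`` ReLU units,
input/hidden dropout, single sigmoid output.  Training: binary
cross-entropy minimised by SGD with momentum 0.7, He-normal
initialisation, and early stopping on monitored balanced accuracy
(patience in epochs, best-epoch weights restored).

Implemented directly on numpy: the networks here are small dense stacks
and the full training loop (forward, backward, momentum update, early
stopping) fits in a few hundred lines while staying bit-reproducible
from a single integer seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .metrics import balanced_accuracy, confusion, sensitivity, specificity


@dataclass(frozen=True)
class HyperparameterSet:
    """One point of the training grid."""

    learning_rate: float
    hidden_units: int
    dropout_input: float
    dropout_hidden: float
    n_layers: int

    def __post_init__(self):
        if not (0.0 <= self.dropout_input < 1.0 and 0.0 <= self.dropout_hidden < 1.0):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.hidden_units < 1 or self.n_layers < 1:
            raise ValueError("hidden_units and n_layers must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainConfig:
    """Fixed (non-searched) training parameters.

    Momentum 0.7 and He-normal initialisation are deliberately constant
    across all networks; only override them for ablations.
    """

    momentum: float = 0.7
    patience: int = 20
    max_epochs: int = 500
    batch_size: int = 128
    threshold: float = 0.5
    network_seed: int = 0
    harmonic_monitor: bool = False

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


class EarlyStopping:
    """Stop when the monitored score has not exceeded its running max
    for ``patience`` consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_score = -np.inf
        self.best_epoch = 0
        self._since_best = 0
        self.epoch = 0

    def update(self, score: float) -> bool:
        """Record one epoch's score; return True if training should stop."""
        self.epoch += 1
        if score > self.best_score:
            self.best_score = score
            self.best_epoch = self.epoch
            self._since_best = 0
        else:
            self._since_best += 1
        return self._since_best >= self.patience


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLPClassifier:
    """Dense ReLU network with a sigmoid output unit."""

    def __init__(self, hp: HyperparameterSet, input_dim: int, cfg: TrainConfig):
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        self.hp = hp
        self.input_dim = input_dim
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.network_seed)
        dims = [input_dim] + [hp.hidden_units] * hp.n_layers + [1]
        # He-normal: std = sqrt(2 / fan_in), biases zero
        self.weights = [
            self.rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self._vel_w = [np.zeros_like(w) for w in self.weights]
        self._vel_b = [np.zeros_like(b) for b in self.biases]
        self.history: list[dict] = []
        self.stopped_epoch: int | None = None

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    # ---- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool):
        """Return (activations, pre-dropout caches) for backprop."""
        hp = self.hp
        masks = []
        a = X
        if training and hp.dropout_input > 0:
            m = (self.rng.random(a.shape) >= hp.dropout_input) / (1 - hp.dropout_input)
            a = a * m
            masks.append(m)
        else:
            masks.append(None)
        acts = [a]
        for i in range(len(self.weights) - 1):
            z = a @ self.weights[i] + self.biases[i]
            a = np.maximum(z, 0.0)
            if training and hp.dropout_hidden > 0:
                m = (self.rng.random(a.shape) >= hp.dropout_hidden) / (1 - hp.dropout_hidden)
                a = a * m
                masks.append(m)
            else:
                masks.append(None)
            acts.append(a)
        z_out = a @ self.weights[-1] + self.biases[-1]
        p = _sigmoid(z_out).ravel()
        return p, acts, masks

    def _backward(self, p: np.ndarray, y: np.ndarray, acts, masks):
        """Gradients of mean BCE; sigmoid+BCE gives delta = p - y."""
        n = len(y)
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = ((p - y) / n)[:, None]
        grads_w[-1] = acts[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        back = delta @ self.weights[-1].T
        for i in range(len(self.weights) - 2, -1, -1):
            if masks[i + 1] is not None:
                back = back * masks[i + 1]
            back = back * (acts[i + 1] > 0)
            grads_w[i] = acts[i].T @ back
            grads_b[i] = back.sum(axis=0)
            if i > 0:
                back = back @ self.weights[i].T
        return grads_w, grads_b

    def _sgd_step(self, grads_w, grads_b, lr: float):
        mu = self.cfg.momentum
        for i in range(len(self.weights)):
            self._vel_w[i] = mu * self._vel_w[i] - lr * grads_w[i]
            self._vel_b[i] = mu * self._vel_b[i] - lr * grads_b[i]
            self.weights[i] += self._vel_w[i]
            self.biases[i] += self._vel_b[i]

    # ---- public API ---------------------------------------------------------

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid outputs in [0, 1]; dropout disabled."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(f"expected shape (n, {self.input_dim}), got {X.shape}")
        p, _, _ = self._forward(X, training=False)
        return p

    def _monitor_score(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_scores(X)
        pred = predict_labels(p, self.cfg.threshold)
        tp, fp, tn, fn = confusion(y, pred)
        return balanced_accuracy(
            sensitivity(tp, fn), specificity(tn, fp), harmonic=self.cfg.harmonic_monitor
        )

    def fit(self, X, y, monitor_X, monitor_y) -> "MLPClassifier":
        """Train with early stopping on monitor-set balanced accuracy."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        mX = np.asarray(monitor_X, dtype=float)
        my = np.asarray(monitor_y, dtype=int).ravel()
        if len(np.unique(y.astype(int))) < 2:
            raise ValueError("training data must contain both classes")
        if len(np.unique(my)) < 2:
            raise ValueError("monitor data must contain both classes (balanced accuracy undefined)")
        stopper = EarlyStopping(self.cfg.patience)
        best_state = None
        n = len(y)
        bs = min(self.cfg.batch_size, n)
        for epoch in range(1, self.cfg.max_epochs + 1):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                p, acts, masks = self._forward(X[idx], training=True)
                eps = 1e-12
                losses.append(
                    float(-np.mean(y[idx] * np.log(p + eps) + (1 - y[idx]) * np.log(1 - p + eps)))
                )
                gw, gb = self._backward(p, y[idx], acts, masks)
                self._sgd_step(gw, gb, self.hp.learning_rate)
            score = self._monitor_score(mX, my)
            self.history.append({"epoch": epoch, "loss": float(np.mean(losses)), "monitor_bacc": score})
            stop = stopper.update(score)
            if stopper.best_epoch == epoch:
                best_state = (copy.deepcopy(self.weights), copy.deepcopy(self.biases))
            if stop:
                break
        # restore best-epoch snapshot (contract: never return worse weights)
        self.weights, self.biases = best_state
        self.stopped_epoch = len(self.history)
        self.best_epoch = stopper.best_epoch
        self.best_monitor_score = float(stopper.best_score)
        return self


def build_network(hp: HyperparameterSet, input_dim: int, cfg: TrainConfig) -> MLPClassifier:
    """Construct an untrained network (He-normal initialised from cfg.network_seed)."""
    return MLPClassifier(hp, input_dim, cfg)


def train(model: MLPClassifier, train_data, monitor_data, cfg: TrainConfig | None = None) -> MLPClassifier:
    """Train ``model`` on (X, y) with early stopping monitored on monitor_data."""
    X, y = train_data
    mX, my = monitor_data
    return model.fit(X, y, mX, my)


def predict_labels(scores, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff score > threshold; a score exactly at the threshold is negative."""
    s = np.asarray(scores, dtype=float)
    return (s > threshold).astype(int)


def save_model(model: MLPClassifier, path, scaler_center=None, scaler_scale=None) -> None:
    """Persist a trained model: architecture JSON + weights npz (+ scaling)."""
    import json
    import os

    os.makedirs(path, exist_ok=True)
    arch = {
        "hyperparameters": model.hp.__dict__,
        "input_dim": model.input_dim,
        "config": {
            "momentum": model.cfg.momentum,
            "patience": model.cfg.patience,
            "max_epochs": model.cfg.max_epochs,
            "batch_size": model.cfg.batch_size,
            "threshold": model.cfg.threshold,
            "network_seed": model.cfg.network_seed,
        },
        "stopped_epoch": model.stopped_epoch,
    }
    with open(os.path.join(path, "architecture.json"), "w") as fh:
        json.dump(arch, fh, indent=2, sort_keys=True)
    arrays = {f"w{i}": w for i, w in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    if scaler_center is not None:
        arrays["scaler_center"] = np.asarray(scaler_center)
        arrays["scaler_scale"] = np.asarray(scaler_scale)
    np.savez(os.path.join(path, "weights.npz"), **arrays)
    if model.history:
        import csv

        with open(os.path.join(path, "history.csv"), "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(model.history[0]))
            w.writeheader()
            w.writerows(model.history)


def load_model(path) -> tuple[MLPClassifier, np.ndarray | None, np.ndarray | None]:
    """Load a model saved by :func:`save_model`; returns (model, center, scale)."""
    import json
    import os

    with open(os.path.join(path, "architecture.json")) as fh:
        arch = json.load(fh)
    hp = HyperparameterSet(**arch["hyperparameters"])
    cfg = TrainConfig(**arch["config"])
    model = MLPClassifier(hp, arch["input_dim"], cfg)
    data = np.load(os.path.join(path, "weights.npz"))
    model.weights = [data[f"w{i}"] for i in range(len(model.weights))]
    model.biases = [data[f"b{i}"] for i in range(len(model.biases))]
    center = data["scaler_center"] if "scaler_center" in data else None
    scale = data["scaler_scale"] if "scaler_scale" in data else None
    return model, center, scale


def ensemble_predict(
    model: MLPClassifier, conformer_groups: Mapping[str, np.ndarray], threshold: float = 0.5
) -> tuple[dict[str, int], dict[str, float]]:
    """Per-compound prediction from a conformer ensemble.

    The compound score is the arithmetic mean of its conformer scores;
    the label follows the same > threshold rule.
    """
    labels: dict[str, int] = {}
    means: dict[str, float] = {}
    for pid, rows in conformer_groups.items():
        rows = np.asarray(rows, dtype=float)
        if rows.size == 0:
            raise ValueError(f"empty conformer group for {pid!r}")
        mean = float(np.mean(model.predict_scores(rows)))
        means[pid] = mean
        labels[pid] = int(mean > threshold)
    return labels, means
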