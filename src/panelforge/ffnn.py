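"""Feed-forward neural network with one hidden layer, trained from scratch.

Logistic sigmoid everywhere, sum-of-squared-errors loss, full-batch
gradient descent via backpropagation.  Class labels use the two-variable
encoding cancer = (1, 0), healthy = (0, 1); the ranking score is the
difference between the two output nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .metrics import auc_score, confusion_from_scores

__all__ = [
    "NetworkArchitecture",
    "TrainingConfig",
    "FFNNModel",
    "CVSummary",
    "TrainingError",
    "DivergenceError",
    "hidden_layer_size",
    "encode_labels",
    "initialize_model",
    "forward",
    "predict_scores",
    "predict_score",
    "sse_loss",
    "gradients",
    "train",
    "cross_validate",
    "stratified_folds",
]

CANCER_TARGET = (1.0, 0.0)
HEALTHY_TARGET = (0.0, 1.0)


class TrainingError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


def hidden_layer_size(n_input: int, n_output: int = 2) -> int:
    """Rule-of-thumb hidden width: midpoint of input and output sizes,
    floored, never below the output size."""
    if n_output < 1 or n_input < n_output:
        raise ValueError("need n_input >= n_output >= 1")
    return max(n_output, (n_input + n_output) // 2)


@dataclass(frozen=True)
class NetworkArchitecture:
    n_input: int
    n_hidden: int
    n_output: int = 2
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.n_output != 2:
            raise ValueError("two-variable encoding requires exactly 2 outputs")
        if self.n_input < 1 or self.n_hidden < 1:
            raise ValueError("layer sizes must be positive")
        if self.activation != "sigmoid":
            raise ValueError(f"unsupported activation {self.activation!r}")

    @classmethod
    def for_panel(cls, panel_size: int) -> "NetworkArchitecture":
        return cls(panel_size, hidden_layer_size(panel_size, 2))


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.05
    max_epochs: int = 200
    weight_init_scale: float = 1.0
    seed: int = 0
    early_stop_patience: int = 0     # 0 disables early stopping
    input_standardization: bool = True

    def __post_init__(self) -> None:
        # learning_rate 0 is tolerated (no-op updates, useful as a degenerate case)
        if self.learning_rate < 0 or self.max_epochs < 1 or self.weight_init_scale <= 0:
            raise ValueError("learning_rate must be >= 0; max_epochs, weight_init_scale positive")
        if self.early_stop_patience < 0:
            raise ValueError("early_stop_patience must be >= 0")


@dataclass
class FFNNModel:
    architecture: NetworkArchitecture
    w1: np.ndarray                   # (n_hidden, n_input)
    b1: np.ndarray                   # (n_hidden,)
    w2: np.ndarray                   # (n_output, n_hidden)
    b2: np.ndarray                   # (n_output,)
    x_mean: np.ndarray | None = None  # training standardization statistics
    x_std: np.ndarray | None = None
    epochs_run: int = 0
    sse_log: list[float] = field(default_factory=list)
    final_sse: float = float("nan")

    def __post_init__(self) -> None:
        a = self.architecture
        if self.w1.shape != (a.n_hidden, a.n_input) or self.b1.shape != (a.n_hidden,):
            raise ValueError("hidden-layer weight shapes inconsistent with architecture")
        if self.w2.shape != (a.n_output, a.n_hidden) or self.b2.shape != (a.n_output,):
            raise ValueError("output-layer weight shapes inconsistent with architecture")

    def copy(self) -> "FFNNModel":
        return FFNNModel(
            self.architecture, self.w1.copy(), self.b1.copy(),
            self.w2.copy(), self.b2.copy(),
            None if self.x_mean is None else self.x_mean.copy(),
            None if self.x_std is None else self.x_std.copy(),
            self.epochs_run, list(self.sse_log), self.final_sse,
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def encode_labels(labels: Sequence[int]) -> np.ndarray:
    """0/1 labels (1 = cancer) -> target rows (cancer=(1,0), healthy=(0,1))."""
    labels = np.asarray(labels, dtype=int)
    targets = np.empty((labels.size, 2))
    targets[labels == 1] = CANCER_TARGET
    targets[labels == 0] = HEALTHY_TARGET
    return targets


def initialize_model(
    arch: NetworkArchitecture, config: TrainingConfig, rng: np.random.Generator | None = None
) -> FFNNModel:
    """Uniform(-w, w) init with w = weight_init_scale / sqrt(fan_in)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w_in = config.weight_init_scale / np.sqrt(arch.n_input)
    w_out = config.weight_init_scale / np.sqrt(arch.n_hidden)
    return FFNNModel(
        arch,
        rng.uniform(-w_in, w_in, size=(arch.n_hidden, arch.n_input)),
        rng.uniform(-w_in, w_in, size=arch.n_hidden),
        rng.uniform(-w_out, w_out, size=(arch.n_output, arch.n_hidden)),
        rng.uniform(-w_out, w_out, size=arch.n_output),
    )


def _standardize(model: FFNNModel, x: np.ndarray) -> np.ndarray:
    if model.x_mean is None:
        return x
    return (x - model.x_mean) / model.x_std


def _forward_batch(model: FFNNModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    hidden = _sigmoid(x @ model.w1.T + model.b1)
    output = _sigmoid(hidden @ model.w2.T + model.b2)
    return hidden, output


def forward(model: FFNNModel, features: Sequence[float]) -> tuple[float, float]:
    """Propagate one feature vector; returns (cancer_score, healthy_score)."""
    x = np.asarray(features, dtype=float)
    if x.shape != (model.architecture.n_input,):
        raise ValueError(
            f"expected {model.architecture.n_input} features, got shape {x.shape}"
        )
    _, out = _forward_batch(model, _standardize(model, x[None, :]))
    return float(out[0, 0]), float(out[0, 1])


def predict_scores(model: FFNNModel, x: np.ndarray) -> np.ndarray:
    """Ranking score cancer_output - healthy_output for each row of ``x``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.architecture.n_input:
        raise ValueError("feature matrix shape inconsistent with architecture")
    _, out = _forward_batch(model, _standardize(model, x))
    return out[:, 0] - out[:, 1]


def predict_score(model: FFNNModel, features: Sequence[float]) -> float:
    c, h = forward(model, features)
    return c - h


def sse_loss(model: FFNNModel, x: np.ndarray, targets: np.ndarray) -> float:
    """Total sum of squared errors over all examples and both outputs."""
    _, out = _forward_batch(model, _standardize(model, x))
    return float(((targets - out) ** 2).sum())


def gradients(
    model: FFNNModel, x: np.ndarray, targets: np.ndarray
) -> dict[str, np.ndarray]:
    """Backpropagation gradients of the total SSE w.r.t. all parameters.

    ``x`` must already be on the network's input scale (standardized if the
    model carries statistics).
    """
    hidden, out = _forward_batch(model, x)
    delta_out = 2.0 * (out - targets) * out * (1.0 - out)
    delta_hidden = (delta_out @ model.w2) * hidden * (1.0 - hidden)
    return {
        "w2": delta_out.T @ hidden,
        "b2": delta_out.sum(axis=0),
        "w1": delta_hidden.T @ x,
        "b1": delta_hidden.sum(axis=0),
    }


def train(
    x: np.ndarray,
    labels: Sequence[int],
    arch: NetworkArchitecture,
    config: TrainingConfig,
    epochs: int | None = None,
    init: FFNNModel | None = None,
) -> FFNNModel:
    """Full-batch gradient descent on the SSE.  Deterministic given seed.

    ``epochs`` overrides ``config.max_epochs`` (e.g. a CV-selected budget).
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if x.ndim != 2 or x.shape[0] != labels.size:
        raise TrainingError("features and labels are inconsistent")
    if len(np.unique(labels)) < 2:
        raise TrainingError("training data contains a single class")
    targets = encode_labels(labels)

    model = init.copy() if init is not None else initialize_model(arch, config)
    if config.input_standardization and model.x_mean is None:
        model.x_mean = x.mean(axis=0)
        std = x.std(axis=0)
        std[std == 0] = 1.0
        model.x_std = std
    xs = _standardize(model, x)

    n_epochs = config.max_epochs if epochs is None else int(epochs)
    lr = config.learning_rate
    best_sse, stall = np.inf, 0
    for epoch in range(1, n_epochs + 1):
        grads = gradients(model, xs, targets)
        model.w1 -= lr * grads["w1"]
        model.b1 -= lr * grads["b1"]
        model.w2 -= lr * grads["w2"]
        model.b2 -= lr * grads["b2"]
        sse = float(((targets - _forward_batch(model, xs)[1]) ** 2).sum())
        if not np.isfinite(sse):
            raise DivergenceError(f"training loss became non-finite at epoch {epoch}")
        model.sse_log.append(sse)
        model.epochs_run = epoch
        if config.early_stop_patience:
            if sse < best_sse - 1e-12:
                best_sse, stall = sse, 0
            else:
                stall += 1
                if stall >= config.early_stop_patience:
                    break
    model.final_sse = model.sse_log[-1] if model.sse_log else sse_loss(model, x, targets)
    return model


def stratified_folds(
    labels: Sequence[int], k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Partition indices into k folds with per-class shuffling."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise TrainingError(f"class {cls} has fewer than k={k} examples")
        idx = rng.permutation(idx)
        for f in range(k):
            folds[f].extend(idx[f::k])
    return [np.sort(np.asarray(f)) for f in folds]


@dataclass
class CVSummary:
    k: int
    fold_auc_curves: np.ndarray      # (k, n_epochs) held-fold AUC per epoch
    mean_auc_curve: np.ndarray       # (n_epochs,)
    best_epoch: int                  # epoch budget maximizing mean held-fold AUC
    best_mean_auc: float
    fold_final_sse: np.ndarray       # (k,)

    @property
    def mean_auc(self) -> float:
        """Mean held-fold AUC at the selected epoch budget."""
        return float(self.mean_auc_curve[self.best_epoch - 1])


def cross_validate(
    x: np.ndarray,
    labels: Sequence[int],
    arch: NetworkArchitecture,
    config: TrainingConfig,
    k: int = 5,
) -> CVSummary:
    """Stratified k-fold CV recording held-fold AUC after every epoch.

    The product is an epoch budget: the epoch maximizing the mean held-fold
    AUC (smallest such epoch on ties).  Deterministic given the seed.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5F01D]))
    folds = stratified_folds(labels, k, rng)
    n_epochs = config.max_epochs

    auc_curves = np.empty((k, n_epochs))
    fold_sse = np.empty(k)
    for f, held in enumerate(folds):
        mask = np.ones(labels.size, dtype=bool)
        mask[held] = False
        x_tr, y_tr = x[mask], labels[mask]
        x_ho, y_ho = x[held], labels[held]
        targets = encode_labels(y_tr)

        model = initialize_model(arch, config, np.random.default_rng(
            np.random.SeedSequence([config.seed, 1 + f])))
        if config.input_standardization:
            model.x_mean = x_tr.mean(axis=0)
            std = x_tr.std(axis=0)
            std[std == 0] = 1.0
            model.x_std = std
        xs = _standardize(model, x_tr)
        lr = config.learning_rate
        for epoch in range(n_epochs):
            grads = gradients(model, xs, targets)
            model.w1 -= lr * grads["w1"]
            model.b1 -= lr * grads["b1"]
            model.w2 -= lr * grads["w2"]
            model.b2 -= lr * grads["b2"]
            auc_curves[f, epoch] = auc_score(predict_scores(model, x_ho), y_ho)
        fold_sse[f] = float(((targets - _forward_batch(model, xs)[1]) ** 2).sum())
        if not np.isfinite(fold_sse[f]):
            raise DivergenceError(f"CV fold {f} diverged")

    mean_curve = auc_curves.mean(axis=0)
    best_epoch = int(np.argmax(mean_curve)) + 1
    return CVSummary(
        k=k,
        fold_auc_curves=auc_curves,
        mean_auc_curve=mean_curve,
        best_epoch=best_epoch,
        best_mean_auc=float(mean_curve[best_epoch - 1]),
        fold_final_sse=fold_sse,
    )
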