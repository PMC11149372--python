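"""Base predictors: L2 logistic regression and a small "pyramid" neural net.

The neural net is the four-layer architecture used throughout the package:
an input layer of K features, one fully connected hidden layer of 100 ReLU
units, a dropout layer (p = 0.5), and a single sigmoid output unit. It is
trained by mini-batch SGD (batch 32) with Nesterov momentum 0.9, initial
learning rate 0.25 decayed as lr_t = lr0 / (1 + 0.003 t) per update, an
elastic-net penalty on the weight matrices (lambda1 |W| + lambda2 ||W||^2,
both 0.001), and early stopping on validation accuracy with best-weight
restoration. Mini-batch gradients are clipped to a global norm of 1.0:
with several hundred input features the 0.25 step combined with momentum
0.9 otherwise diverges in the first epoch. Implemented directly on NumPy arrays; training is fully
deterministic given the seed.

Logistic regression wraps scikit-learn's solver; the two predictors share
the ``TrainedPredictor`` surface so downstream schemes are model-agnostic.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

_EPS = 1e-7


@dataclass
class DNNConfig:
    hidden_nodes: int = 100
    dropout_p: float = 0.5
    learning_rate: float = 0.25
    batch_size: int = 32
    max_epochs: int = 200
    momentum: float = 0.9
    lr_decay: float = 0.003
    patience: int = 200
    lambda1: float = 0.001
    lambda2: float = 0.001
    clip_norm: float = 1.0  # global gradient-norm cap; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        for name in ("learning_rate", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedPredictor:
    """A fitted scoring function mapping feature vectors to case probability."""

    kind: str  # "LR" or "DNN"
    parameters: dict
    history: dict = field(default_factory=dict)
    n_features: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# logistic regression


def train_lr(
    X_train: np.ndarray,
    y_train: np.ndarray,
    l2_strength: float = 1.0,
    seed: int = 0,
    max_iter: int = 1000,
) -> TrainedPredictor:
    """L2-penalized logistic regression (stochastic-average-gradient solver).

    ``l2_strength`` is the penalty weight (scikit-learn C = 1/l2_strength).
    Non-convergence at max_iter is reported as a warning; the fit is still
    returned.
    """
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = LogisticRegression(
        penalty="l2",
        C=1.0 / l2_strength,
        solver="sag",
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X_train, y)
    converged = int(clf.n_iter_[0]) < max_iter
    if not converged:
        warnings.warn("logistic regression did not converge", RuntimeWarning)
    return TrainedPredictor(
        kind="LR",
        parameters={"coef": clf.coef_[0].copy(), "intercept": float(clf.intercept_[0])},
        history={"n_iter": int(clf.n_iter_[0]), "converged": converged},
        n_features=X_train.shape[1],
    )


# ---------------------------------------------------------------------------
# pyramid DNN


def _init_params(k: int, config: DNNConfig, rng: np.random.Generator) -> dict:
    """Glorot-uniform initialization, biases at zero."""
    h = config.hidden_nodes
    if h > 0:
        lim1 = np.sqrt(6.0 / (k + h))
        lim2 = np.sqrt(6.0 / (h + 1))
        return {
            "W1": rng.uniform(-lim1, lim1, size=(k, h)),
            "b1": np.zeros(h),
            "W2": rng.uniform(-lim2, lim2, size=(h, 1)),
            "b2": np.zeros(1),
        }
    lim = np.sqrt(6.0 / (k + 1))
    return {"W2": rng.uniform(-lim, lim, size=(k, 1)), "b2": np.zeros(1)}


def _forward(params: dict, X: np.ndarray, drop_mask: np.ndarray | None = None):
    if "W1" in params:
        a = X @ params["W1"] + params["b1"]
        h = np.maximum(a, 0.0)
        if drop_mask is not None:
            h = h * drop_mask
        p = _sigmoid(h @ params["W2"] + params["b2"])[:, 0]
        return p, a, h
    p = _sigmoid(X @ params["W2"] + params["b2"])[:, 0]
    return p, None, X


def _penalty(params: dict, l1: float, l2: float) -> float:
    tot = 0.0
    for key in ("W1", "W2"):
        if key in params:
            tot += l1 * np.abs(params[key]).sum()
            tot += l2 * (params[key] ** 2).sum()
    return float(tot)


def _full_loss(params: dict, X: np.ndarray, y: np.ndarray, config: DNNConfig) -> float:
    """Training objective per the printed form: summed BCE plus penalties."""
    p, _, _ = _forward(params, X)
    n = len(y)
    return n * _bce(y, p) + _penalty(params, config.lambda1, config.lambda2)


def train_dnn(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: DNNConfig | None = None,
    init_params: dict | None = None,
    step_offset: int = 0,
) -> TrainedPredictor:
    """Train the pyramid net by seeded mini-batch SGD with Nesterov momentum.

    ``init_params`` warm-starts from existing weights (used by fine-tuning);
    otherwise weights are Glorot-initialized from the config seed.
    ``step_offset`` advances the learning-rate decay schedule as if that many
    updates had already happened — fine-tuning continues the pretraining
    schedule instead of restarting at the full step size. The parameters
    achieving the best validation accuracy are restored at the end. Raises
    on NaN loss.
    """
    config = config or DNNConfig()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if X_val is None or len(X_val) == 0:
        raise ValueError("validation set must be non-empty")
    Xv = np.asarray(X_val, dtype=float)
    yv = np.asarray(y_val, dtype=float)
    k = X.shape[1]
    rng = np.random.default_rng(config.seed)
    params = (
        {key: v.copy() for key, v in init_params.items()}
        if init_params is not None
        else _init_params(k, config, rng)
    )
    velocity = {key: np.zeros_like(v) for key, v in params.items()}
    n = X.shape[0]
    # the objective sums BCE over individuals and adds the penalties once;
    # batches optimize mean BCE, so the penalty coefficients scale by 1/n
    l1 = config.lambda1 / n
    l2 = config.lambda2 / n
    step = int(step_offset)
    best_acc, best_params, best_epoch = -np.inf, copy.deepcopy(params), 0
    epochs_since_best = 0
    train_losses: list[float] = []
    val_accs: list[float] = []

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            nb = len(idx)
            if config.dropout_p > 0 and "W1" in params:
                mask = (
                    rng.random((nb, config.hidden_nodes)) >= config.dropout_p
                ) / (1.0 - config.dropout_p)
            else:
                mask = None
            p, a, h = _forward(params, xb, mask)
            delta = (p - yb)[:, None] / nb  # d(mean BCE)/d(logit)
            grads = {"W2": h.T @ delta, "b2": delta.sum(axis=0)}
            if "W1" in params:
                dh = delta @ params["W2"].T
                if mask is not None:
                    dh = dh * mask
                da = dh * (a > 0)
                grads["W1"] = xb.T @ da
                grads["b1"] = da.sum(axis=0)
            for key in ("W1", "W2"):
                if key in grads:
                    grads[key] += l1 * np.sign(params[key])
                    grads[key] += 2.0 * l2 * params[key]
            if config.clip_norm > 0:
                gnorm = np.sqrt(sum((g**2).sum() for g in grads.values()))
                if gnorm > config.clip_norm:
                    for key in grads:
                        grads[key] *= config.clip_norm / gnorm
            lr = config.learning_rate / (1.0 + config.lr_decay * step)
            step += 1
            for key in params:
                v = config.momentum * velocity[key] - lr * grads[key]
                velocity[key] = v
                params[key] = params[key] + config.momentum * v - lr * grads[key]

        loss = _full_loss(params, X, y, config)
        if not np.isfinite(loss):
            raise RuntimeError(f"NaN/inf training loss at epoch {epoch}")
        train_losses.append(loss)
        pv, _, _ = _forward(params, Xv)
        acc = float(((pv >= 0.5) == (yv >= 0.5)).mean())
        val_accs.append(acc)
        if acc > best_acc:
            best_acc, best_epoch = acc, epoch
            best_params = copy.deepcopy(params)
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break

    return TrainedPredictor(
        kind="DNN",
        parameters=best_params,
        history={
            "train_loss": train_losses,
            "val_accuracy": val_accs,
            "best_epoch": best_epoch,
            "steps": step,
            "config": config,
        },
        n_features=k,
    )


def save_predictor(model: TrainedPredictor, path) -> None:
    """Serialize a fitted model to a portable JSON container.

    Weights are stored as nested lists; the training configuration is
    echoed for provenance. History curves are included when present.
    """
    import dataclasses
    import json
    from pathlib import Path

    payload = {
        "kind": model.kind,
        "n_features": model.n_features,
        "parameters": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in model.parameters.items()
        },
        "history": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in model.history.items()
            if k in ("config", "train_loss", "val_accuracy", "best_epoch",
                     "steps", "n_iter", "converged", "fine_tuned")
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_predictor(path) -> TrainedPredictor:
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    params = {
        k: (np.asarray(v) if isinstance(v, list) else v)
        for k, v in payload["parameters"].items()
    }
    history = payload.get("history", {})
    if isinstance(history.get("config"), dict):
        history["config"] = DNNConfig(**history["config"])
    return TrainedPredictor(
        kind=payload["kind"],
        parameters=params,
        history=history,
        n_features=payload["n_features"],
    )


def predict(model: TrainedPredictor, X: np.ndarray) -> np.ndarray:
    """Case probabilities in (0,1); dropout inactive, fully deterministic."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature count {X.shape[1]} does not match training ({model.n_features})"
        )
    if model.kind == "LR":
        z = X @ model.parameters["coef"] + model.parameters["intercept"]
        p = _sigmoid(z)
    else:
        p, _, _ = _forward(model.parameters, X)
    return np.clip(p, _EPS, 1.0 - _EPS)
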